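"""Sequence alphabets.

An :class:`Alphabet` bundles the ordered letter set, the complement map and
the background letter frequencies. The DNA alphabet with uniform background
is provided as :data:`DNA`; use :func:`dna` for a custom background
composition. Any letter set with an involutive complement map works, so
user-declared alphabets (e.g. with modified bases) are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = ["Alphabet", "DNA", "dna", "reverse_complement"]

_TOL = 1e-9


@dataclass(frozen=True)
class Alphabet:
    """Ordered letter set with complement map and background frequencies.

    Parameters
    ----------
    letters
        Ordered, unique single characters (e.g. ``"ACGT"``).
    complement
        Mapping letter -> letter; must be an involution over ``letters``.
    background_freqs
        Probability of each letter, in ``letters`` order; sums to 1.
    """

    letters: tuple[str, ...]
    complement: Mapping[str, str]
    background_freqs: np.ndarray = field(repr=False)

    def __init__(
        self,
        letters: Sequence[str] | str,
        complement: Mapping[str, str],
        background_freqs: Sequence[float] | None = None,
    ) -> None:
        letters = tuple(letters)
        if len(set(letters)) != len(letters):
            raise ConfigurationError(f"alphabet letters not unique: {letters!r}")
        if any(len(l) != 1 for l in letters):
            raise ConfigurationError("alphabet letters must be single characters")
        for l in letters:
            if l not in complement:
                raise ConfigurationError(f"letter {l!r} has no complement")
            if complement[complement[l]] != l:
                raise ConfigurationError(
                    f"complement map is not an involution at letter {l!r}"
                )
        if background_freqs is None:
            freqs = np.full(len(letters), 1.0 / len(letters))
        else:
            freqs = np.asarray(background_freqs, dtype=float)
        if freqs.shape != (len(letters),):
            raise ConfigurationError(
                f"background_freqs has length {freqs.size}, expected {len(letters)}"
            )
        if (freqs < 0).any() or abs(freqs.sum() - 1.0) > _TOL:
            raise ConfigurationError(
                "background_freqs must be nonnegative and sum to 1"
            )
        object.__setattr__(self, "letters", letters)
        object.__setattr__(self, "complement", dict(complement))
        object.__setattr__(self, "background_freqs", freqs)
        object.__setattr__(
            self, "_index", {l: i for i, l in enumerate(letters)}
        )

    @property
    def size(self) -> int:
        return len(self.letters)

    def index(self, letter: str) -> int:
        try:
            return self._index[letter]  # type: ignore[attr-defined]
        except KeyError:
            raise ConfigurationError(f"letter {letter!r} not in alphabet") from None

    def indices(self, sequence: str) -> np.ndarray:
        """Encode a sequence as an integer array of letter indices."""
        idx = self._index  # type: ignore[attr-defined]
        try:
            return np.fromiter((idx[c] for c in sequence), dtype=np.intp,
                               count=len(sequence))
        except KeyError as exc:
            from .errors import DataError

            raise DataError(
                f"letter {exc.args[0]!r} not in alphabet {''.join(self.letters)!r}"
            ) from None

    def decode(self, indices: np.ndarray) -> str:
        arr = np.asarray(self.letters)
        return "".join(arr[indices])

    def complement_permutation(self) -> np.ndarray:
        """Index permutation mapping each letter column to its complement."""
        return np.array([self.index(self.complement[l]) for l in self.letters])

    def contains(self, sequence: str) -> bool:
        return all(c in self._index for c in sequence)  # type: ignore[attr-defined]


def reverse_complement(sequence: str, alphabet: Alphabet) -> str:
    """Reverse complement of ``sequence`` under the alphabet's complement map.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    comp = alphabet.complement
    try:
        return "".join(comp[c] for c in reversed(sequence))
    except KeyError as exc:
        from .errors import DataError

        raise DataError(f"letter {exc.args[0]!r} has no complement") from None


def dna(background_freqs: Sequence[float] | None = None) -> Alphabet:
    """DNA alphabet (ACGT, Watson-Crick complement) with optional background."""
    return Alphabet(
        "ACGT",
        {"A": "T", "T": "A", "C": "G", "G": "C"},
        background_freqs,
    )


#: DNA with uniform background frequencies.
DNA = dna()
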
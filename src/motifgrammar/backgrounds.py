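"""Background sequence pools.

Backgrounds are the substrate motif instances are implanted into. Four
sources are supported:

* i.i.d. simulation from the alphabet's letter frequencies, with lengths
  uniform on a configured range;
* user FASTA, imported as-is;
* mononucleotide shuffling of user sequences (letter multiset preserved);
* an order-k Markov chain trained on user sequences and sampled afresh.

Each pool optionally carries *generative tracks*: per-position letter
distributions describing how each sequence was generated. I.i.d. pools get
the analytic background distribution at every position; for imported,
shuffled and Markov pools the generative distribution of the realized
sequence is represented as the one-hot track of its letters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import Alphabet, DNA
from .errors import ConfigurationError, DataError, SamplingError

__all__ = [
    "BackgroundPool",
    "MarkovModel",
    "simulate_iid",
    "import_fasta",
    "mononucleotide_shuffle",
    "shuffle_pool",
    "fit_markov",
    "sample_markov",
    "markov_pool",
    "one_hot_track",
    "write_fasta",
]


def one_hot_track(sequence: str, alphabet: Alphabet) -> np.ndarray:
    """One-hot per-position letter distribution of a realized sequence."""
    track = np.zeros((len(sequence), alphabet.size))
    track[np.arange(len(sequence)), alphabet.indices(sequence)] = 1.0
    return track


@dataclass
class BackgroundPool:
    """Background sequences plus generative tracks and provenance.

    ``records`` is an ordered list of ``(id, sequence)`` pairs; ``tracks``
    (if present) holds one (length x alphabet size) probability array per
    record; ``source`` is one of ``iid``, ``imported``, ``shuffled``,
    ``markov``.
    """

    records: list[tuple[str, str]]
    alphabet: Alphabet = DNA
    tracks: list[np.ndarray] | None = None
    source: str = "iid"

    def __post_init__(self) -> None:
        if self.tracks is not None and len(self.tracks) != len(self.records):
            raise ConfigurationError("one generative track per sequence required")
        if self.tracks is not None:
            for (sid, seq), tr in zip(self.records, self.tracks):
                if tr.shape != (len(seq), self.alphabet.size):
                    raise ConfigurationError(
                        f"track shape {tr.shape} mismatches sequence {sid!r} "
                        f"of length {len(seq)}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def track_for(self, index: int) -> np.ndarray:
        """Generative track of record ``index`` (one-hot if none stored)."""
        if self.tracks is not None:
            return self.tracks[index]
        return one_hot_track(self.records[index][1], self.alphabet)


def _random_sequences(
    lengths: np.ndarray,
    freqs: np.ndarray,
    alphabet: Alphabet,
    rng: np.random.Generator,
) -> list[str]:
    # draw all letters at once; split per sequence (fast path for large n)
    lut = np.frombuffer("".join(alphabet.letters).encode("ascii"), dtype=np.uint8)
    total = int(lengths.sum())
    idx = rng.choice(alphabet.size, size=total, p=freqs)
    raw = lut[idx].tobytes().decode("ascii")
    out, pos = [], 0
    for L in lengths:
        out.append(raw[pos : pos + int(L)])
        pos += int(L)
    return out


def simulate_iid(
    n: int,
    len_min: int,
    len_max: int,
    alphabet: Alphabet,
    rng: np.random.Generator,
) -> BackgroundPool:
    """Simulate ``n`` i.i.d. sequences with lengths uniform on [len_min, len_max].

    Every position's generative distribution is the alphabet background, so
    the pool's tracks are constant rows of ``alphabet.background_freqs``.
    """
    if not (1 <= len_min <= len_max):
        raise ConfigurationError(
            f"need 1 <= len_min <= len_max, got ({len_min}, {len_max})"
        )
    if n < 0:
        raise ConfigurationError(f"n must be >= 0, got {n}")
    lengths = rng.integers(len_min, len_max + 1, size=n)
    seqs = _random_sequences(lengths, alphabet.background_freqs, alphabet, rng)
    records = [(f"background_{i}", s) for i, s in enumerate(seqs)]
    tracks = [
        np.tile(alphabet.background_freqs, (int(L), 1)) for L in lengths
    ]
    return BackgroundPool(records, alphabet, tracks, source="iid")


def import_fasta(
    path: str | Path,
    alphabet: Alphabet = DNA,
    on_invalid: str = "error",
    rng: np.random.Generator | None = None,
) -> BackgroundPool:
    """Import background sequences from FASTA, used as-is (uppercased).

    Ids are taken verbatim up to the first whitespace. Letters outside the
    alphabet are rejected by default; with ``on_invalid="resample"`` they
    are replaced by draws from the background frequencies.
    """
    if on_invalid not in ("error", "resample"):
        raise ConfigurationError(f"unknown on_invalid policy {on_invalid!r}")
    records: list[tuple[str, str]] = []
    letters = set(alphabet.letters)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = [i for i, c in enumerate(seq) if c not in letters]
        if bad:
            if on_invalid == "error":
                raise DataError(
                    f"{path}: sequence {rec.id!r} has non-alphabet letter "
                    f"{seq[bad[0]]!r} at position {bad[0]}"
                )
            if rng is None:
                raise ConfigurationError("resampling invalid letters needs an rng")
            arr = list(seq)
            draws = rng.choice(
                alphabet.size, size=len(bad), p=alphabet.background_freqs
            )
            for i, d in zip(bad, draws):
                arr[i] = alphabet.letters[d]
            seq = "".join(arr)
        records.append((rec.id, seq))
    if not records:
        raise DataError(f"{path}: no FASTA records found")
    tracks = [one_hot_track(s, alphabet) for _, s in records]
    return BackgroundPool(records, alphabet, tracks, source="imported")


def mononucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Uniformly random permutation of a sequence's letters."""
    if not sequence:
        raise DataError("cannot shuffle an empty sequence")
    arr = np.array(list(sequence))
    rng.shuffle(arr)
    return "".join(arr)


def shuffle_pool(pool: BackgroundPool, rng: np.random.Generator) -> BackgroundPool:
    """Mononucleotide-shuffle every sequence in a pool."""
    records = [
        (sid, mononucleotide_shuffle(seq, rng)) for sid, seq in pool.records
    ]
    tracks = [one_hot_track(s, pool.alphabet) for _, s in records]
    return BackgroundPool(records, pool.alphabet, tracks, source="shuffled")


@dataclass
class MarkovModel:
    """Order-k Markov chain over an alphabet.

    ``transition`` maps each observed length-k context to a probability
    vector over letters; ``initial`` is the distribution over starting
    contexts. ``pseudocount > 0`` additionally defines a uniform row for
    contexts never observed in training.
    """

    order: int
    transition: dict[str, np.ndarray]
    initial: dict[str, float]
    alphabet: Alphabet = DNA
    pseudocount: float = 0.0
    _cumulative: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def row(self, context: str) -> np.ndarray:
        try:
            return self.transition[context]
        except KeyError:
            if self.pseudocount > 0:
                return np.full(self.alphabet.size, 1.0 / self.alphabet.size)
            raise SamplingError(
                f"context {context!r} unseen in training and pseudocount is 0"
            ) from None

    def _cum_row(self, context: str) -> np.ndarray:
        cum = self._cumulative.get(context)
        if cum is None:
            cum = np.cumsum(self.row(context))
            self._cumulative[context] = cum
        return cum


def fit_markov(
    sequences: Sequence[str],
    order: int,
    alphabet: Alphabet = DNA,
    pseudocount: float = 0.0,
) -> MarkovModel:
    """Fit an order-k Markov chain by counting (k+1)-mers.

    ``transition[c][x]`` is proportional to the count of context ``c``
    followed by letter ``x``, plus the pseudocount. The initial context
    distribution is the empirical distribution of each training sequence's
    first k letters. Order 0 reduces to an i.i.d. letter model with the
    single empty context.
    """
    if order < 0:
        raise ConfigurationError(f"order must be >= 0, got {order}")
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be >= 0")
    if not sequences:
        raise DataError("no training sequences")
    shortest = min(len(s) for s in sequences)
    if order >= shortest and order > 0:
        raise DataError(
            f"order {order} >= shortest training sequence length {shortest}"
        )

    counts: dict[str, np.ndarray] = {}
    initial_counts: dict[str, float] = {}
    index = {l: i for i, l in enumerate(alphabet.letters)}
    for seq in sequences:
        for c in seq:
            if c not in index:
                raise DataError(f"letter {c!r} not in alphabet")
        start = seq[:order]
        initial_counts[start] = initial_counts.get(start, 0.0) + 1.0
        for i in range(order, len(seq)):
            ctx = seq[i - order : i]
            row = counts.get(ctx)
            if row is None:
                row = counts[ctx] = np.zeros(alphabet.size)
            row[index[seq[i]]] += 1.0

    transition: dict[str, np.ndarray] = {}
    for ctx, row in counts.items():
        smoothed = row + pseudocount
        total = smoothed.sum()
        if total == 0:
            continue  # context observed only at sequence ends with pc=0
        transition[ctx] = smoothed / total
    z = sum(initial_counts.values())
    initial = {c: v / z for c, v in initial_counts.items()}
    return MarkovModel(order, transition, initial, alphabet, pseudocount)


def sample_markov(
    model: MarkovModel, length: int, rng: np.random.Generator
) -> str:
    """Sample one sequence of the given length from a fitted Markov chain."""
    if length < model.order:
        raise ConfigurationError(
            f"length {length} shorter than model order {model.order}"
        )
    contexts = list(model.initial)
    probs = np.array([model.initial[c] for c in contexts])
    start = contexts[rng.choice(len(contexts), p=probs)]
    out = list(start[:length])
    letters = model.alphabet.letters
    u = rng.random(max(length - len(out), 0))
    for step in range(length - len(out)):
        ctx = "".join(out[-model.order :]) if model.order else ""
        cum = model._cum_row(ctx)
        out.append(letters[int(np.searchsorted(cum, u[step] * cum[-1]))])
    return "".join(out)


def markov_pool(
    model: MarkovModel,
    n: int,
    len_min: int,
    len_max: int,
    rng: np.random.Generator,
) -> BackgroundPool:
    """Sample ``n`` sequences from a Markov model, lengths uniform on bounds."""
    if not (1 <= len_min <= len_max):
        raise ConfigurationError(
            f"need 1 <= len_min <= len_max, got ({len_min}, {len_max})"
        )
    lengths = rng.integers(max(len_min, model.order), len_max + 1, size=n)
    records = [
        (f"background_{i}", sample_markov(model, int(L), rng))
        for i, L in enumerate(lengths)
    ]
    tracks = [one_hot_track(s, model.alphabet) for _, s in records]
    return BackgroundPool(records, model.alphabet, tracks, source="markov")


def write_fasta(
    records: Sequence[tuple[str, str]], path: str | Path, width: int = 80
) -> None:
    """Write ``(id, sequence)`` pairs as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
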
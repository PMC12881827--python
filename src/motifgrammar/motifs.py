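"""Motif model, simulation, information content, multimers, and motif I/O.

A motif is a position frequency matrix (PFM): one probability vector over
the alphabet per position. Motifs are either simulated (lengths uniform on
a configured range, columns drawn from a Dirichlet distribution whose
concentration controls the average information content per position),
imported from MEME-minimal or JASPAR files, or assembled from other motifs
as multimers with fixed — possibly negative — spacings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .alphabet import DNA, Alphabet
from .errors import ConfigurationError, DataError, ParseError

__all__ = [
    "Motif",
    "MotifSet",
    "MotifSimSpec",
    "MultimerRule",
    "simulate_motifs",
    "information_content",
    "expected_information_content",
    "calibrate_concentration",
    "multimerize",
    "read_motifs",
    "write_meme",
]

_COLUMN_TOL = 1e-9


@dataclass
class Motif:
    """A position frequency matrix with an identifier.

    ``matrix`` has shape (length, alphabet size); every row is a probability
    vector. ``source`` records provenance: ``"simulated"``, ``"imported"``
    or ``"multimer"``.
    """

    id: str
    matrix: np.ndarray
    source: str = "simulated"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1:
            raise ConfigurationError(
                f"motif {self.id!r}: matrix must be 2-D with length >= 1"
            )
        if (self.matrix < -_COLUMN_TOL).any():
            raise ConfigurationError(f"motif {self.id!r}: negative probabilities")
        sums = self.matrix.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ConfigurationError(
                f"motif {self.id!r}: columns do not sum to 1 (max dev "
                f"{np.abs(sums - 1.0).max():.2e})"
            )

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def consensus(self, alphabet: Alphabet) -> str:
        """Most probable letter at each position (ties broken by letter order)."""
        return "".join(alphabet.letters[i] for i in self.matrix.argmax(axis=1))


class MotifSet:
    """Ordered collection of motifs with unique ids, tied to an alphabet."""

    def __init__(self, motifs: Sequence[Motif] = (), alphabet: Alphabet = DNA):
        self.alphabet = alphabet
        self._motifs: dict[str, Motif] = {}
        for m in motifs:
            self.add(m)

    def add(self, motif: Motif) -> None:
        if motif.id in self._motifs:
            raise ConfigurationError(f"duplicate motif id {motif.id!r}")
        if motif.matrix.shape[1] != self.alphabet.size:
            raise ConfigurationError(
                f"motif {motif.id!r}: {motif.matrix.shape[1]} columns per "
                f"position, alphabet has {self.alphabet.size} letters"
            )
        self._motifs[motif.id] = motif

    @property
    def ids(self) -> list[str]:
        return list(self._motifs)

    def __getitem__(self, motif_id: str) -> Motif:
        try:
            return self._motifs[motif_id]
        except KeyError:
            raise ConfigurationError(f"unknown motif id {motif_id!r}") from None

    def __contains__(self, motif_id: str) -> bool:
        return motif_id in self._motifs

    def __iter__(self) -> Iterator[Motif]:
        return iter(self._motifs.values())

    def __len__(self) -> int:
        return len(self._motifs)


@dataclass
class MotifSimSpec:
    """Parameters for motif simulation.

    ``alpha`` is the per-letter concentration vector of the Dirichlet
    distribution each PFM column is drawn from: small alpha gives sharp,
    high-information columns; large alpha gives near-uniform columns.
    """

    n_motifs: int
    len_min: int
    len_max: int
    alphabet: Alphabet = DNA
    alpha: Sequence[float] | float = 1.0

    def __post_init__(self) -> None:
        if self.n_motifs < 1:
            raise ConfigurationError(f"n_motifs must be >= 1, got {self.n_motifs}")
        if not (1 <= self.len_min <= self.len_max):
            raise ConfigurationError(
                f"need 1 <= len_min <= len_max, got len_min={self.len_min}, "
                f"len_max={self.len_max}"
            )
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.ndim == 0:
            alpha = np.full(self.alphabet.size, float(alpha))
        if alpha.shape != (self.alphabet.size,):
            raise ConfigurationError(
                f"alpha has length {alpha.size}, alphabet has "
                f"{self.alphabet.size} letters"
            )
        if (alpha <= 0).any():
            raise ConfigurationError("alpha entries must all be > 0")
        self.alpha = alpha


@dataclass
class MultimerRule:
    """Recipe for a composite motif.

    ``spacings[i]`` is the gap between component ``i`` and ``i+1``; negative
    values overlap the components. ``weights`` mix overlapping columns.
    """

    component_ids: Sequence[str]
    spacings: Sequence[int]
    weights: Sequence[float] | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        if len(self.component_ids) < 1:
            raise ConfigurationError("multimer needs at least one component")
        if len(self.spacings) != len(self.component_ids) - 1:
            raise ConfigurationError(
                f"multimer needs {len(self.component_ids) - 1} spacings, "
                f"got {len(self.spacings)}"
            )
        if self.weights is None:
            self.weights = [1.0] * len(self.component_ids)
        if len(self.weights) != len(self.component_ids):
            raise ConfigurationError("one weight per component required")
        if any(w < 0 for w in self.weights):
            raise ConfigurationError("multimer weights must be nonnegative")
        if not any(w > 0 for w in self.weights):
            raise ConfigurationError("at least one multimer weight must be > 0")


def simulate_motifs(spec: MotifSimSpec, rng: np.random.Generator) -> MotifSet:
    """Draw ``spec.n_motifs`` motifs.

    Lengths are uniform on [len_min, len_max]; each column is an independent
    Dirichlet(alpha) draw. Ids are ``motif_0``, ``motif_1``, ... in draw
    order.
    """
    out = MotifSet(alphabet=spec.alphabet)
    lengths = rng.integers(spec.len_min, spec.len_max + 1, size=spec.n_motifs)
    for k, length in enumerate(lengths):
        matrix = rng.dirichlet(spec.alpha, size=int(length))
        out.add(Motif(id=f"motif_{k}", matrix=matrix, source="simulated"))
    return out


def information_content(motif: Motif) -> tuple[np.ndarray, float]:
    """Per-position and mean information content in bits.

    IC at a position is log2(alphabet size) minus the Shannon entropy of
    that column; 0*log(0) is taken as 0. Ranges from 0 (uniform column) to
    log2(alphabet size) (one-hot column).
    """
    p = motif.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = -plogp.sum(axis=1)
    per_position = np.log2(p.shape[1]) - entropy
    per_position = np.clip(per_position, 0.0, None)
    return per_position, float(per_position.mean())


def expected_information_content(
    alpha: float,
    alphabet_size: int = 4,
    n_columns: int = 20_000,
    seed: int = 2026,
) -> float:
    """Monte-Carlo estimate of E[IC] for a symmetric Dirichlet(alpha) column.

    A fixed internal seed makes the estimate a deterministic, monotone
    decreasing function of ``alpha`` suitable for bisection.
    """
    if alpha <= 0:
        raise ConfigurationError("alpha must be > 0")
    rng = np.random.default_rng(seed)
    cols = rng.dirichlet([alpha] * alphabet_size, size=n_columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(cols > 0, cols * np.log2(cols), 0.0)
    ic = np.log2(alphabet_size) + plogp.sum(axis=1)
    return float(ic.mean())


def calibrate_concentration(
    target_mean_ic: float,
    alphabet_size: int = 4,
    tol: float = 0.02,
    n_columns: int = 20_000,
    seed: int = 2026,
    max_iter: int = 60,
) -> float:
    """Find a symmetric Dirichlet concentration with the requested mean IC.

    Bisection (in log alpha) on the Monte-Carlo expectation of per-column
    information content, which decreases monotonically in alpha. Returns an
    alpha whose Monte-Carlo E[IC] is within ``tol`` bits of the target.
    """
    max_ic = math.log2(alphabet_size)
    if not (0.0 < target_mean_ic < max_ic):
        raise ConfigurationError(
            f"target mean IC must lie strictly between 0 and "
            f"log2({alphabet_size}) = {max_ic:.3f} bits, got {target_mean_ic}"
        )

    def f(log_alpha: float) -> float:
        return expected_information_content(
            math.exp(log_alpha), alphabet_size, n_columns, seed
        )

    lo, hi = math.log(1e-4), math.log(1e4)  # alpha bracket
    if f(lo) < target_mean_ic or f(hi) > target_mean_ic:
        raise ConfigurationError(
            f"target IC {target_mean_ic} bits unreachable within the "
            "concentration bracket [1e-4, 1e4]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        ic = f(mid)
        if abs(ic - target_mean_ic) <= tol:
            return math.exp(mid)
        if ic > target_mean_ic:  # column too sharp -> raise alpha
            lo = mid
        else:
            hi = mid
    raise ConfigurationError(
        f"calibration did not converge to within {tol} bits of "
        f"{target_mean_ic} in {max_iter} iterations"
    )


def multimerize(
    motifs: MotifSet,
    rule: MultimerRule,
    motif_id: str | None = None,
) -> Motif:
    """Lay components along a shared axis and merge into one motif.

    Component i+1 starts where component i ends, plus ``spacings[i]``
    (negative spacings overlap). Positions covered by exactly one component
    take its column; positions covered by none take the alphabet background
    distribution; overlapped positions take the weight-normalized convex
    combination of the covering columns. Every output column is a
    probability vector.
    """
    comps = [motifs[cid] for cid in rule.component_ids]
    weights = np.asarray(rule.weights, dtype=float)

    starts: list[int] = [0]
    for comp, gap in zip(comps[:-1], rule.spacings):
        starts.append(starts[-1] + comp.length + int(gap))
    ends = [s + c.length for s, c in zip(starts, comps)]
    origin = min(starts)
    total = max(ends) - origin
    if total < 1:
        raise ConfigurationError("multimer layout has length < 1")

    A = motifs.alphabet.size
    acc = np.zeros((total, A))
    wsum = np.zeros(total)
    cover = np.zeros(total, dtype=int)
    solo = np.zeros((total, A))  # column when exactly one component covers
    for comp, w, s in zip(comps, weights, starts):
        sl = slice(s - origin, s - origin + comp.length)
        acc[sl] += w * comp.matrix
        wsum[sl] += w
        cover[sl] += 1
        solo[sl] = comp.matrix
    overlapped = cover >= 2
    if (overlapped & (wsum == 0)).any():
        raise DataError(
            "all-zero weights over an overlapped position in multimer"
        )
    out = np.empty_like(acc)
    out[cover == 0] = motifs.alphabet.background_freqs
    out[cover == 1] = solo[cover == 1]  # weights only arbitrate overlaps
    out[overlapped] = acc[overlapped] / wsum[overlapped, None]
    out /= out.sum(axis=1, keepdims=True)

    mid = motif_id or rule.id or "multimer_" + "+".join(rule.component_ids)
    return Motif(id=mid, matrix=out, source="multimer")


# ---------------------------------------------------------------------------
# Motif file I/O


def _motif_from_counts(name: str, counts: np.ndarray, source_path: str) -> Motif:
    sums = counts.sum(axis=1)
    if (sums <= 0).any():
        raise DataError(
            f"{source_path}: motif {name!r} has a zero-sum count column"
        )
    return Motif(id=name, matrix=counts / sums[:, None], source="imported")


def _read_meme_logodds(path: Path, alphabet: Alphabet) -> MotifSet:
    """Fallback for MEME files that carry only log-odds matrices.

    Probabilities are recovered by a softmax against the file's declared
    background: p_i proportional to b_i * 2**score_i. Lossy relative to the
    original PFM because printed log-odds are rounded.
    """
    lines = path.read_text().splitlines()
    background = np.asarray(alphabet.background_freqs, dtype=float)
    out = MotifSet(alphabet=alphabet)
    name = None
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            if i + 1 < n_lines:
                toks = lines[i + 1].split()
                freqs = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks) - 1, 2)}
                if set(freqs) >= set(alphabet.letters):
                    background = np.array([freqs[l] for l in alphabet.letters])
        if line.startswith("MOTIF"):
            name = line.split()[1]
        if line.startswith("log-odds matrix"):
            if name is None:
                raise ParseError(f"{path}, line {i + 1}: matrix before MOTIF header")
            toks = line.split()
            try:
                width = int(toks[toks.index("w=") + 1])
            except (ValueError, IndexError):
                raise ParseError(
                    f"{path}, line {i + 1}: missing 'w=' width in log-odds header"
                ) from None
            rows = []
            for j in range(width):
                try:
                    rows.append([float(x) for x in lines[i + 1 + j].split()])
                except (IndexError, ValueError):
                    raise ParseError(
                        f"{path}, line {i + 2 + j}: bad log-odds row for "
                        f"motif {name!r}"
                    ) from None
            scores = np.asarray(rows)
            probs = background * np.exp2(scores)
            probs /= probs.sum(axis=1, keepdims=True)
            out.add(Motif(id=name, matrix=probs, source="imported"))
            i += width
        i += 1
    if len(out) == 0:
        raise ParseError(f"{path}: no log-odds matrices found")
    return out


def read_motifs(path: str | Path, format: str, alphabet: Alphabet = DNA) -> MotifSet:
    """Read motifs from a MEME-minimal or JASPAR PFM file.

    JASPAR counts are normalized to probabilities with no pseudocount; a
    zero-sum count column is an error. MEME files whose records carry only
    log-odds matrices are converted to probabilities by softmax against the
    declared background (lossy).
    """
    path = Path(path)
    fmt = format.lower()
    if fmt not in ("meme", "jaspar"):
        raise ConfigurationError(f"unknown motif format {format!r}")
    dialect = "minimal" if fmt == "meme" else "jaspar"
    try:
        with open(path) as handle:
            records = bio_motifs.parse(handle, dialect)
    except FileNotFoundError:
        raise
    except Exception as exc:
        if fmt == "meme" and "letter-probability" in path.read_text():
            raise ParseError(f"{path} ({fmt}): {exc}") from exc
        if fmt == "meme" and "log-odds matrix" in path.read_text():
            return _read_meme_logodds(path, alphabet)
        raise ParseError(f"{path} ({fmt}): {exc}") from exc

    if fmt == "meme" and any(rec.length == 0 for rec in records):
        # letter-probability blocks absent; fall back to log-odds if present
        if "log-odds matrix" in path.read_text():
            return _read_meme_logodds(path, alphabet)
        raise ParseError(f"{path}: motif with no letter-probability matrix")

    out = MotifSet(alphabet=alphabet)
    for rec in records:
        letters = "".join(alphabet.letters)
        rec_letters = "".join(rec.alphabet)
        if sorted(rec_letters) != sorted(letters):
            raise ParseError(
                f"{path}: motif alphabet {rec_letters!r} does not match "
                f"expected {letters!r}"
            )
        name = getattr(rec, "matrix_id", None) or rec.name or f"motif_{len(out)}"
        counts = np.array([[rec.counts[l][i] for l in alphabet.letters]
                           for i in range(rec.length)], dtype=float)
        out.add(_motif_from_counts(str(name), counts, str(path)))
    if len(out) == 0:
        raise ParseError(f"{path}: no motifs found")
    return out


def _quantized_column(column: np.ndarray, scale: int = 1_000_000) -> np.ndarray:
    """Round a probability vector to 1/scale units summing exactly to scale.

    Largest-remainder rounding; each entry moves by less than 1/scale, so
    printing with 6 decimals stays within 1e-6 of the true column while the
    printed values sum to exactly 1.000000 (needed for a lossless read-back).
    """
    scaled = column * scale
    units = np.floor(scaled).astype(np.int64)
    short = scale - int(units.sum())
    if short > 0:
        order = np.argsort(-(scaled - units), kind="stable")
        units[order[:short]] += 1
    return units / scale


def write_meme(
    motifs: MotifSet,
    path: str | Path,
    nsites: int = 1_000_000,
) -> None:
    """Write a MotifSet in MEME v4 minimal format.

    Probabilities are printed with 6 decimal places, per-column normalized
    to sum to exactly 1; ``read_motifs`` reproduces the columns to within
    1e-6.
    """
    alphabet = motifs.alphabet
    letters = "".join(alphabet.letters)
    lines = [
        "MEME version 4",
        "",
        f"ALPHABET= {letters}",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(
            f"{l} {f:.6f}" for l, f in zip(letters, alphabet.background_freqs)
        ),
        "",
    ]
    for m in motifs:
        lines.append(f"MOTIF {m.id}")
        lines.append(
            f"letter-probability matrix: alength= {alphabet.size} "
            f"w= {m.length} nsites= {nsites} E= 0"
        )
        for row in m.matrix:
            lines.append(" ".join(f"{v:.6f}" for v in _quantized_column(row)))
        lines.append("")
    Path(path).write_text("\n".join(lines))
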
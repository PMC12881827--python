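"""Per-sequence sampling and implantation.

Each simulated sequence is produced by one *round*: draw a background from
the pool, the number of instances to implant, a group chain from the
grammar, one motif per group, one concrete instance string per motif, an
orientation (Bernoulli) and a position (center / uniform / Gaussian) per
instance, then write the instances into the background. Implantation
*replaces* background letters, so sequence length, coordinates and
probability tracks all stay aligned with the background.

Reproducibility: a single master seed spawns one child random stream per
round, so each round's draws are independent of evaluation order and the
whole run is reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .alphabet import Alphabet, reverse_complement
from .backgrounds import BackgroundPool
from .errors import ConfigurationError, PlacementError
from .grammar import Grammar, sample_groups, sample_motif_from_group
from .motifs import Motif, MotifSet

__all__ = [
    "InsertionPolicy",
    "InsertionRecord",
    "SimulationResult",
    "sample_num_instances",
    "sample_instance",
    "sample_position",
    "place_instance",
    "simulate_round",
    "run_simulation",
]

logger = logging.getLogger(__name__)

_BOUNDARY_TRIES = 10_000


@dataclass
class InsertionPolicy:
    """How many instances to implant, and with what orientation/position.

    count_dist
        ``("fixed", n)`` or ``("poisson", lam)``.
    p_forward
        Probability an instance keeps the motif orientation ('+').
    position_dist
        ``("center",)``, ``("uniform",)`` or ``("gaussian", mean_offset, sd)``
        where the Gaussian is centered on the middle placement plus
        ``mean_offset`` with standard deviation ``sd`` (positions).
    overlap_policy
        ``"allow"`` places instances regardless of overlap (later draws
        overwrite earlier letters; both keep records, the earlier flagged
        occluded); ``"resample"`` redraws the position up to ``max_tries``
        times and drops the instance if no overlap-free position is found.
    boundary_policy
        For Gaussian draws outside the valid range: ``"resample"`` redraws,
        ``"clip"`` clamps to the nearest valid start.
    """

    count_dist: tuple = ("fixed", 1)
    p_forward: float = 0.5
    position_dist: tuple = ("uniform",)
    overlap_policy: str = "resample"
    max_tries: int = 100
    boundary_policy: str = "resample"

    def __post_init__(self) -> None:
        kind = self.count_dist[0]
        if kind == "fixed":
            if int(self.count_dist[1]) < 0:
                raise ConfigurationError("fixed instance count must be >= 0")
        elif kind == "poisson":
            if float(self.count_dist[1]) < 0:
                raise ConfigurationError("Poisson rate must be >= 0")
        else:
            raise ConfigurationError(f"unknown count distribution {kind!r}")
        if not (0.0 <= self.p_forward <= 1.0):
            raise ConfigurationError("p_forward must be in [0, 1]")
        pkind = self.position_dist[0]
        if pkind not in ("center", "uniform", "gaussian"):
            raise ConfigurationError(f"unknown position distribution {pkind!r}")
        if pkind == "gaussian" and float(self.position_dist[2]) < 0:
            raise ConfigurationError("Gaussian position sd must be >= 0")
        if self.overlap_policy not in ("allow", "resample"):
            raise ConfigurationError(
                f"unknown overlap policy {self.overlap_policy!r}"
            )
        if self.max_tries < 1:
            raise ConfigurationError("max_tries must be >= 1")
        if self.boundary_policy not in ("resample", "clip"):
            raise ConfigurationError(
                f"unknown boundary policy {self.boundary_policy!r}"
            )


@dataclass
class InsertionRecord:
    """Ground truth for one implanted motif instance.

    Coordinates are 0-based half-open on the output sequence. ``instance``
    is the string as sampled from the motif; on strand '-' the sequence
    carries its reverse complement at [start, end). ``occluded`` marks
    records whose letters were later overwritten by another instance
    (only possible under the ``allow`` overlap policy).
    """

    sequence_id: str
    motif_id: str
    group_id: str
    instance: str
    start: int
    end: int
    strand: str
    draw_index: int
    occluded: bool = False


@dataclass
class SimulationResult:
    """Complete output bundle of a simulation run."""

    sequences: list[tuple[str, str]]
    records: list[InsertionRecord]
    probability_tracks: list[np.ndarray]
    counts: dict[str, Any]
    provenance: dict[str, Any]
    backgrounds: BackgroundPool | None = None
    alphabet: Alphabet | None = None


def sample_num_instances(
    policy: InsertionPolicy, rng: np.random.Generator
) -> int:
    """Number of instances for one sequence: fixed or Poisson."""
    kind, value = policy.count_dist[0], policy.count_dist[1]
    if kind == "fixed":
        return int(value)
    return int(rng.poisson(float(value)))


def sample_instance(
    motif: Motif, alphabet: Alphabet, rng: np.random.Generator
) -> str:
    """Draw a concrete instance string: letter i ~ column i, independently."""
    cum = np.cumsum(motif.matrix, axis=1)
    u = rng.random(motif.length)
    idx = np.minimum(
        (cum < u[:, None]).sum(axis=1), alphabet.size - 1
    )
    return "".join(alphabet.letters[i] for i in idx)


def sample_position(
    policy: InsertionPolicy,
    seq_len: int,
    motif_len: int,
    rng: np.random.Generator,
) -> int:
    """Draw a start coordinate for an instance of ``motif_len`` letters.

    ``center`` is deterministic at floor((seq_len - motif_len) / 2);
    ``uniform`` is an integer uniform on [0, seq_len - motif_len];
    ``gaussian`` rounds a real draw centered on the middle placement, with
    the boundary policy applied when the draw falls outside the valid
    range.
    """
    if motif_len > seq_len:
        raise PlacementError(
            f"motif of length {motif_len} does not fit in sequence of "
            f"length {seq_len}"
        )
    hi = seq_len - motif_len
    kind = policy.position_dist[0]
    if kind == "center":
        return hi // 2
    if kind == "uniform":
        return int(rng.integers(0, hi + 1))
    _, mean_offset, sd = policy.position_dist
    center = hi // 2
    for _ in range(_BOUNDARY_TRIES):
        pos = int(round(center + float(mean_offset) + float(sd) * rng.standard_normal()))
        if 0 <= pos <= hi:
            return pos
        if policy.boundary_policy == "clip":
            return min(max(pos, 0), hi)
    raise PlacementError(
        f"Gaussian position draw never landed in [0, {hi}] after "
        f"{_BOUNDARY_TRIES} tries (offset {mean_offset}, sd {sd})"
    )


def place_instance(sequence: str, instance: str, start: int) -> str:
    """Write ``instance`` over ``sequence`` at ``start`` (length preserved)."""
    if not (0 <= start <= len(sequence) - len(instance)):
        raise PlacementError(
            f"start {start} with instance length {len(instance)} out of "
            f"range for sequence of length {len(sequence)}"
        )
    return sequence[:start] + instance + sequence[start + len(instance):]


def _overlaps(start: int, end: int, intervals: list[tuple[int, int]]) -> bool:
    return any(start < e and s < end for s, e in intervals)


def simulate_round(
    background: tuple[str, str],
    background_track: np.ndarray,
    grammar: Grammar,
    motifs: MotifSet,
    policy: InsertionPolicy,
    alphabet: Alphabet,
    rng: np.random.Generator,
    sequence_id: str,
) -> tuple[str, list[InsertionRecord], np.ndarray, int]:
    """One sampling round: implant a grammar draw into one background.

    Returns the final sequence, its insertion records, its per-position
    letter-probability track, and the number of instances dropped by the
    resample overlap policy.
    """
    _, sequence = background
    track = background_track.copy()
    k = sample_num_instances(policy, rng)
    groups = sample_groups(grammar, k, rng)
    motif_ids = [sample_motif_from_group(grammar, g, rng) for g in groups]

    comp_perm = alphabet.complement_permutation()
    records: list[InsertionRecord] = []
    placed: list[tuple[int, int]] = []
    dropped = 0
    for i, (group_id, motif_id) in enumerate(zip(groups, motif_ids)):
        motif = motifs[motif_id]
        instance = sample_instance(motif, alphabet, rng)
        strand = "+" if rng.random() < policy.p_forward else "-"
        start: int | None = None
        if policy.overlap_policy == "resample":
            for _ in range(policy.max_tries):
                cand = sample_position(policy, len(sequence), motif.length, rng)
                if not _overlaps(cand, cand + motif.length, placed):
                    start = cand
                    break
            if start is None:
                dropped += 1
                warnings.warn(
                    f"{sequence_id}: dropped instance of {motif_id} after "
                    f"{policy.max_tries} overlapping position draws",
                    stacklevel=2,
                )
                continue
        else:
            start = sample_position(policy, len(sequence), motif.length, rng)
        end = start + motif.length
        written = instance if strand == "+" else reverse_complement(instance, alphabet)
        sequence = place_instance(sequence, written, start)
        rows = motif.matrix if strand == "+" else motif.matrix[::-1, comp_perm]
        track[start:end] = rows
        placed.append((start, end))
        records.append(
            InsertionRecord(
                sequence_id=sequence_id,
                motif_id=motif_id,
                group_id=group_id,
                instance=instance,
                start=start,
                end=end,
                strand=strand,
                draw_index=i,
            )
        )

    # later placements occlude earlier overlapping ones (allow policy only)
    for a in range(len(records)):
        for b in range(a + 1, len(records)):
            if records[a].start < records[b].end and records[b].start < records[a].end:
                records[a].occluded = True
    return sequence, records, track, dropped


def run_simulation(
    backgrounds: BackgroundPool,
    motifs: MotifSet,
    grammar: Grammar,
    policy: InsertionPolicy,
    n_sequences: int,
    seed: int | np.random.SeedSequence,
    provenance: dict[str, Any] | None = None,
) -> SimulationResult:
    """Run ``n_sequences`` sampling rounds and tally all sampled entities.

    Backgrounds are drawn uniformly with replacement from the pool, so the
    pool may be smaller than ``n_sequences``. Output ids are
    ``sequence_0`` ... in round order. The result is fully determined by
    the inputs and ``seed``.
    """
    if n_sequences < 0:
        raise ConfigurationError("n_sequences must be >= 0")
    if len(backgrounds) == 0 and n_sequences > 0:
        raise ConfigurationError("background pool is empty")
    for mid in grammar.motif_ids:
        if mid not in motifs:
            raise ConfigurationError(
                f"grammar references motif {mid!r} absent from the motif set"
            )

    alphabet = backgrounds.alphabet
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_sequences) if n_sequences else []
    sequences: list[tuple[str, str]] = []
    tracks: list[np.ndarray] = []
    all_records: list[InsertionRecord] = []
    tally = {
        key: Counter()
        for key in (
            "backgrounds", "groups", "motifs", "orientations", "instances",
            "instances_per_sequence", "positions", "motif_lengths",
        )
    }
    total_dropped = 0

    for i in range(n_sequences):
        rng = np.random.default_rng(children[i])
        bg_index = int(rng.integers(len(backgrounds)))
        bg = backgrounds.records[bg_index]
        sid = f"sequence_{i}"
        try:
            seq, records, track, dropped = simulate_round(
                bg, backgrounds.track_for(bg_index), grammar, motifs,
                policy, alphabet, rng, sid,
            )
        except Exception as exc:
            raise type(exc)(f"round {i}: {exc}") from exc
        sequences.append((sid, seq))
        tracks.append(track)
        all_records.extend(records)
        total_dropped += dropped

        tally["backgrounds"][bg[0]] += 1
        tally["instances_per_sequence"][str(len(records))] += 1
        for rec in records:
            tally["groups"][rec.group_id] += 1
            tally["motifs"][rec.motif_id] += 1
            tally["orientations"][rec.strand] += 1
            tally["instances"][rec.instance] += 1
            tally["positions"][str(rec.start)] += 1
            tally["motif_lengths"][str(rec.end - rec.start)] += 1

    counts: dict[str, Any] = {k: dict(v) for k, v in tally.items()}
    counts["dropped_instances"] = total_dropped
    if total_dropped:
        logger.warning("%d instances dropped by overlap resampling", total_dropped)

    prov = dict(provenance or {})
    if isinstance(seed, (int, np.integer)):
        prov.setdefault("seed", int(seed))
    prov.setdefault("n_sequences", n_sequences)
    return SimulationResult(
        sequences=sequences,
        records=all_records,
        probability_tracks=tracks,
        counts=counts,
        provenance=prov,
        backgrounds=backgrounds,
        alphabet=alphabet,
    )
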
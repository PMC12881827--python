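"""Direct modification of user-provided sequences.

Supports masking intervals, single-nucleotide substitution, shifting a
motif site along its sequence, and implanting an instance at an exact
position — the operations needed to perturb real regulatory sequences for
model-explainability experiments. All coordinates are 0-based half-open
(BED convention) and every edit preserves sequence length.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import Alphabet, DNA, reverse_complement
from .errors import ConfigurationError, DataError, ParseError, PlacementError
from .sampler import InsertionRecord, place_instance

__all__ = [
    "EditInstruction",
    "mask_interval",
    "substitute_base",
    "shift_site",
    "implant_at",
    "apply_edits",
    "read_edit_instructions",
]


def _check_interval(sequence: str, start: int, end: int) -> None:
    if not (0 <= start <= end <= len(sequence)):
        raise PlacementError(
            f"interval [{start}, {end}) out of bounds for sequence of "
            f"length {len(sequence)}"
        )


def mask_interval(sequence: str, interval: tuple[int, int], mask_letter: str) -> str:
    """Replace every position in [start, end) with ``mask_letter`` (e.g. 'N')."""
    start, end = interval
    _check_interval(sequence, start, end)
    if len(mask_letter) != 1:
        raise ConfigurationError("mask letter must be a single character")
    return sequence[:start] + mask_letter * (end - start) + sequence[end:]


def substitute_base(sequence: str, position: int, letter: str) -> str:
    """Replace the letter at ``position``."""
    if not (0 <= position < len(sequence)):
        raise PlacementError(
            f"position {position} out of bounds for sequence of length "
            f"{len(sequence)}"
        )
    if len(letter) != 1:
        raise ConfigurationError("substitution letter must be a single character")
    return sequence[:position] + letter + sequence[position + 1:]


def shift_site(
    sequence: str,
    interval: tuple[int, int],
    delta: int,
    fill: str = "background",
    alphabet: Alphabet = DNA,
    rng: np.random.Generator | None = None,
) -> tuple[str, tuple[int, int]]:
    """Move the site at ``interval`` by ``delta`` positions.

    The site string is written at the shifted interval (the site wins where
    old and new intervals overlap); vacated positions are filled either
    with a fixed letter (``fill='A'``) or with draws from the alphabet
    background frequencies (``fill='background'``, requires ``rng``).
    Returns the edited sequence and the new interval.
    """
    start, end = interval
    _check_interval(sequence, start, end)
    new_start, new_end = start + delta, end + delta
    if not (0 <= new_start and new_end <= len(sequence)):
        raise PlacementError(
            f"shift by {delta} pushes site [{start}, {end}) out of the "
            f"sequence bounds [0, {len(sequence)})"
        )
    site = sequence[start:end]
    out = list(sequence)
    vacated = [i for i in range(start, end) if not (new_start <= i < new_end)]
    if fill == "background":
        if rng is None:
            raise ConfigurationError("background fill requires an rng")
        draws = rng.choice(
            alphabet.size, size=len(vacated), p=alphabet.background_freqs
        )
        for i, d in zip(vacated, draws):
            out[i] = alphabet.letters[d]
    else:
        if len(fill) != 1:
            raise ConfigurationError(
                f"fill must be 'background' or a single letter, got {fill!r}"
            )
        for i in vacated:
            out[i] = fill
    out[new_start:new_end] = site
    return "".join(out), (new_start, new_end)


def implant_at(
    sequence: str,
    instance: str,
    start: int,
    strand: str = "+",
    alphabet: Alphabet = DNA,
    sequence_id: str = "",
    motif_id: str = "",
    draw_index: int = 0,
) -> tuple[str, InsertionRecord]:
    """Implant an instance at an exact position, returning the ground truth.

    On strand '-' the reverse complement is written; the record stores the
    instance as given, so reading the sequence back at [start, end) and
    reverse-complementing reproduces it.
    """
    if strand not in ("+", "-"):
        raise ConfigurationError(f"strand must be '+' or '-', got {strand!r}")
    written = instance if strand == "+" else reverse_complement(instance, alphabet)
    edited = place_instance(sequence, written, start)
    record = InsertionRecord(
        sequence_id=sequence_id,
        motif_id=motif_id or instance,
        group_id="",
        instance=instance,
        start=start,
        end=start + len(instance),
        strand=strand,
        draw_index=draw_index,
    )
    return edited, record


@dataclass
class EditInstruction:
    """One edit on one sequence.

    ``op`` is one of ``mask``, ``substitute``, ``shift``, ``implant``.
    ``payload`` is the mask letter, substitution letter, or instance
    string; ``delta`` the shift offset; ``fill`` either ``background`` or
    a single letter; ``strand`` applies to implants.
    """

    sequence_id: str
    op: str
    start: int
    end: int = 0
    payload: str = ""
    delta: int = 0
    fill: str = "background"
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.op not in ("mask", "substitute", "shift", "implant"):
            raise ConfigurationError(f"unknown edit op {self.op!r}")
        if self.op == "substitute" and self.end not in (0, self.start + 1):
            raise ConfigurationError(
                "substitute instructions must have end = start + 1"
            )


def apply_edits(
    records: list[tuple[str, str]],
    instructions: list[EditInstruction],
    alphabet: Alphabet = DNA,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], list[InsertionRecord]]:
    """Apply a batch of instructions, in order, to named sequences.

    Returns the edited records and the insertion records produced by
    implants (other ops leave no record). Instructions for unknown
    sequence ids are an error.
    """
    seqs = dict(records)
    order = [sid for sid, _ in records]
    implant_records: list[InsertionRecord] = []
    implant_count: dict[str, int] = {}
    for ins in instructions:
        if ins.sequence_id not in seqs:
            raise DataError(f"edit for unknown sequence id {ins.sequence_id!r}")
        seq = seqs[ins.sequence_id]
        try:
            seqs[ins.sequence_id], rec = _apply_one(ins, seq, alphabet, rng,
                                                    implant_count)
        except (PlacementError, DataError, ConfigurationError) as exc:
            raise type(exc)(f"sequence {ins.sequence_id!r}: {exc}") from exc
        if rec is not None:
            implant_records.append(rec)
    return [(sid, seqs[sid]) for sid in order], implant_records


def _apply_one(
    ins: EditInstruction,
    seq: str,
    alphabet: Alphabet,
    rng: np.random.Generator | None,
    implant_count: dict[str, int],
) -> tuple[str, InsertionRecord | None]:
    if ins.op == "mask":
        return mask_interval(seq, (ins.start, ins.end), ins.payload or "N"), None
    if ins.op == "substitute":
        if ins.payload not in alphabet.letters:
            raise DataError(f"substitution letter {ins.payload!r} not in alphabet")
        return substitute_base(seq, ins.start, ins.payload), None
    if ins.op == "shift":
        out, _ = shift_site(
            seq, (ins.start, ins.end), ins.delta, ins.fill, alphabet, rng
        )
        return out, None
    # implant
    k = implant_count.get(ins.sequence_id, 0)
    out, rec = implant_at(
        seq, ins.payload, ins.start, ins.strand, alphabet,
        sequence_id=ins.sequence_id, draw_index=k,
    )
    implant_count[ins.sequence_id] = k + 1
    return out, rec


def read_edit_instructions(path: str | Path) -> list[EditInstruction]:
    """Read edit instructions from a TSV file.

    Columns: sequence_id, op, start, end, payload, delta, fill, strand.
    A header row naming the first column ``sequence_id`` is skipped.
    Empty trailing columns take their defaults.
    """
    out: list[EditInstruction] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0] == "sequence_id":
                continue
            row = row + [""] * (8 - len(row))
            try:
                out.append(
                    EditInstruction(
                        sequence_id=row[0],
                        op=row[1],
                        start=int(row[2]),
                        end=int(row[3]) if row[3] else 0,
                        payload=row[4],
                        delta=int(row[5]) if row[5] else 0,
                        fill=row[6] or "background",
                        strand=row[7] or "+",
                    )
                )
            except (ValueError, ConfigurationError) as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
    return out
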
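"""Output bundle writers.

A complete run writes, into one directory:

* ``sequences.fasta`` — the final sequences with instances implanted;
* ``backgrounds.fasta`` — the background pool;
* ``instances.bed`` — BED6 ground truth (chrom = sequence id, 0-based
  half-open, name = motif id, score = draw index, strand);
* ``details.csv`` — one row per implanted instance with all draw details;
* ``counts.json`` — tallies of every sampled entity class;
* ``motifs.meme`` — the motif set in MEME v4 minimal format;
* four ``cooccurrence_*.tsv`` matrices implied by the grammar;
* ``sequence_probabilities.npz`` / ``background_probabilities.npz`` —
  per-position letter-probability arrays, one named (length x alphabet
  size) array per sequence id.

Floats in text outputs are printed with 6 significant digits, and the
array archives are written deterministically, so a config + seed pair
yields a byte-identical bundle.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .backgrounds import write_fasta
from .config import OutputToggles
from .errors import OutputError
from .grammar import Grammar, implied_cooccurrence
from .motifs import MotifSet, write_meme
from .sampler import SimulationResult

__all__ = ["write_bundle", "write_tracks_text", "read_bed"]

_COOC_FILES = {
    "group_conditional": "cooccurrence_group_conditional.tsv",
    "motif_marginal": "cooccurrence_motif_marginal.tsv",
    "motif_joint": "cooccurrence_motif_joint.tsv",
    "motif_conditional": "cooccurrence_motif_conditional.tsv",
}


def write_tracks_text(
    tracks: Mapping[str, np.ndarray], path: str | Path, letters: Iterable[str]
) -> None:
    """Plain-text fallback for the probability archives.

    TSV with columns sequence_id, position, then one probability column
    per alphabet letter.
    """
    letters = list(letters)
    with open(path, "w") as fh:
        fh.write("sequence_id\tposition\t" + "\t".join(letters) + "\n")
        for sid, track in tracks.items():
            for pos, row in enumerate(track):
                fh.write(
                    f"{sid}\t{pos}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n"
                )


def _bed_rows(result: SimulationResult) -> Iterable[str]:
    for rec in result.records:
        yield (
            f"{rec.sequence_id}\t{rec.start}\t{rec.end}\t{rec.motif_id}\t"
            f"{rec.draw_index}\t{rec.strand}\n"
        )


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 file back into a DataFrame (for round-trip checks)."""
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )


def write_bundle(
    result: SimulationResult,
    outdir: str | Path,
    motifs: MotifSet | None = None,
    grammar: Grammar | None = None,
    toggles: OutputToggles | None = None,
    overwrite: bool = False,
) -> list[Path]:
    """Write the full output bundle; returns the paths written.

    Refuses to overwrite existing files unless ``overwrite`` is set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    toggles = toggles or OutputToggles()

    planned: list[str] = []
    if toggles.sequences:
        planned.append("sequences.fasta")
    if toggles.backgrounds and result.backgrounds is not None:
        planned.append("backgrounds.fasta")
    if toggles.bed:
        planned.append("instances.bed")
    if toggles.csv:
        planned.append("details.csv")
    if toggles.counts:
        planned.append("counts.json")
    if toggles.meme and motifs is not None:
        planned.append("motifs.meme")
    if toggles.cooccurrence and grammar is not None:
        planned.extend(_COOC_FILES.values())
    if toggles.probability_arrays:
        planned.append("sequence_probabilities.npz")
        if result.backgrounds is not None and result.backgrounds.tracks is not None:
            planned.append("background_probabilities.npz")
    if toggles.text_tracks:
        planned.append("sequence_probabilities.tsv")

    if not overwrite:
        existing = [name for name in planned if (outdir / name).exists()]
        if existing:
            raise OutputError(
                f"refusing to overwrite {', '.join(existing)} in {outdir} "
                "(pass overwrite=True / --overwrite)"
            )

    written: list[Path] = []

    def done(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    if toggles.sequences:
        write_fasta(result.sequences, done("sequences.fasta"))
    if toggles.backgrounds and result.backgrounds is not None:
        write_fasta(result.backgrounds.records, done("backgrounds.fasta"))
    if toggles.bed:
        with open(done("instances.bed"), "w") as fh:
            fh.writelines(_bed_rows(result))
    if toggles.csv:
        df = pd.DataFrame(
            [
                {
                    "sequence_id": r.sequence_id,
                    "motif_id": r.motif_id,
                    "group_id": r.group_id,
                    "instance": r.instance,
                    "start": r.start,
                    "end": r.end,
                    "strand": r.strand,
                    "draw_index": r.draw_index,
                    "occluded": r.occluded,
                }
                for r in result.records
            ],
            columns=[
                "sequence_id", "motif_id", "group_id", "instance", "start",
                "end", "strand", "draw_index", "occluded",
            ],
        )
        df.to_csv(done("details.csv"), index=False)
    if toggles.counts:
        with open(done("counts.json"), "w") as fh:
            json.dump(result.counts, fh, indent=2, sort_keys=True)
            fh.write("\n")
    if toggles.meme and motifs is not None:
        write_meme(motifs, done("motifs.meme"))
    if toggles.cooccurrence and grammar is not None:
        tables = implied_cooccurrence(grammar)
        for key, fname in _COOC_FILES.items():
            tables[key].to_csv(done(fname), sep="\t", float_format="%.6g")
    if toggles.probability_arrays:
        np.savez_compressed(
            done("sequence_probabilities.npz"),
            **{sid: tr for (sid, _), tr in
               zip(result.sequences, result.probability_tracks)},
        )
        if result.backgrounds is not None and result.backgrounds.tracks is not None:
            np.savez_compressed(
                done("background_probabilities.npz"),
                **{sid: tr for (sid, _), tr in
                   zip(result.backgrounds.records, result.backgrounds.tracks)},
            )
    if toggles.text_tracks:
        letters = result.alphabet.letters if result.alphabet else ()
        write_tracks_text(
            {sid: tr for (sid, _), tr in
             zip(result.sequences, result.probability_tracks)},
            done("sequence_probabilities.tsv"),
            letters,
        )
    return written
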
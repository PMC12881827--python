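"""The unified run configuration.

A single YAML document controls everything: background creation, motif
creation, multimer rules, the co-occurrence grammar, the insertion policy,
the number of sequences, the master seed and the output toggles. Unknown
keys are rejected (typo protection) and every constraint violation names
the offending key.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigurationError, ParseError

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AlphabetConfig(_Strict):
    letters: str = "ACGT"
    complement: dict[str, str] | None = None
    background_freqs: list[float] | None = None


class BackgroundConfig(_Strict):
    mode: Literal["iid", "fasta", "shuffle", "markov"] = "iid"
    n: int = Field(default=100, ge=0)
    len_min: int = Field(default=200, ge=1)
    len_max: int = Field(default=200, ge=1)
    fasta: str | None = None
    markov_order: int = Field(default=1, ge=0)
    pseudocount: float = Field(default=0.0, ge=0.0)
    on_invalid: Literal["error", "resample"] = "error"

    @model_validator(mode="after")
    def _check(self) -> "BackgroundConfig":
        if self.len_min > self.len_max:
            raise ValueError("backgrounds.len_min exceeds backgrounds.len_max")
        if self.mode in ("fasta", "shuffle", "markov") and not self.fasta:
            raise ValueError(
                f"backgrounds.fasta is required for mode {self.mode!r}"
            )
        return self


class MotifConfig(_Strict):
    mode: Literal["simulate", "file"] = "simulate"
    n_motifs: int = Field(default=1, ge=1)
    len_min: int = Field(default=8, ge=1)
    len_max: int = Field(default=12, ge=1)
    alpha: float | list[float] | None = None
    target_mean_ic: float | None = Field(default=None, gt=0.0)
    path: str | None = None
    format: Literal["meme", "jaspar"] = "meme"

    @model_validator(mode="after")
    def _check(self) -> "MotifConfig":
        if self.len_min > self.len_max:
            raise ValueError("motifs.len_min exceeds motifs.len_max")
        if self.mode == "file" and not self.path:
            raise ValueError("motifs.path is required for mode 'file'")
        if self.alpha is not None and self.target_mean_ic is not None:
            raise ValueError(
                "motifs.alpha and motifs.target_mean_ic are mutually exclusive"
            )
        if isinstance(self.alpha, (int, float)) and self.alpha <= 0:
            raise ValueError("motifs.alpha must be > 0")
        if isinstance(self.alpha, list) and any(a <= 0 for a in self.alpha):
            raise ValueError("motifs.alpha entries must all be > 0")
        return self


class MultimerConfig(_Strict):
    id: str
    components: list[str] = Field(min_length=1)
    spacings: list[int]
    weights: list[float] | None = None


class GrammarConfig(_Strict):
    groups: dict[str, list[str]] | None = None
    group_marginal: list[float] | None = None
    group_conditional: list[list[float]] | None = None
    motif_within_group: dict[str, list[float]] | None = None


class CountConfig(_Strict):
    dist: Literal["fixed", "poisson"] = "fixed"
    n: int = Field(default=1, ge=0)
    lam: float = Field(default=1.0, ge=0.0)


class PositionConfig(_Strict):
    dist: Literal["center", "uniform", "gaussian"] = "uniform"
    mean_offset: float = 0.0
    sd: float = Field(default=0.0, ge=0.0)


class OverlapConfig(_Strict):
    policy: Literal["allow", "resample"] = "resample"
    max_tries: int = Field(default=100, ge=1)


class InsertionConfig(_Strict):
    count: CountConfig = CountConfig()
    p_forward: float = Field(default=0.5, ge=0.0, le=1.0)
    position: PositionConfig = PositionConfig()
    overlap: OverlapConfig = OverlapConfig()
    boundary: Literal["resample", "clip"] = "resample"


class OutputToggles(_Strict):
    sequences: bool = True
    backgrounds: bool = True
    bed: bool = True
    csv: bool = True
    counts: bool = True
    meme: bool = True
    cooccurrence: bool = True
    probability_arrays: bool = True
    text_tracks: bool = False


class RunConfig(_Strict):
    """Top-level configuration for a simulation run."""

    n_sequences: int = Field(ge=0)
    seed: int = Field(default=0, ge=0)
    outdir: str | None = None
    alphabet: AlphabetConfig = AlphabetConfig()
    backgrounds: BackgroundConfig = BackgroundConfig()
    motifs: MotifConfig = MotifConfig()
    multimers: list[MultimerConfig] = []
    grammar: GrammarConfig = GrammarConfig()
    insertion: InsertionConfig = InsertionConfig()
    outputs: OutputToggles = OutputToggles()


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(path: str | Path) -> RunConfig:
    """Load and fully validate a YAML run configuration.

    Unknown keys, malformed probability tables and missing referenced
    files are all reported with the offending key or path.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise ParseError(f"{path}: YAML parse error{where}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: configuration must be a YAML mapping")
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(
            f"{path}: {_format_validation_error(exc)}"
        ) from exc

    base = path.parent
    for key, rel in (
        ("backgrounds.fasta", cfg.backgrounds.fasta),
        ("motifs.path", cfg.motifs.path),
    ):
        if rel is not None:
            resolved = (base / rel) if not Path(rel).is_absolute() else Path(rel)
            if not resolved.exists():
                raise ConfigurationError(
                    f"{path}: {key} refers to missing file {resolved}"
                )
            # store resolved path so downstream code is cwd-independent
            section, attr = key.split(".")
            setattr(getattr(cfg, section), attr, str(resolved))
    return cfg
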
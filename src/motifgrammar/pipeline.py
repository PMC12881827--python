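"""Assemble and run a simulation from a :class:`RunConfig`.

Seeding layout: the master seed spawns three fixed child streams —
backgrounds, motifs, and the per-round simulation — so adding sequences
never changes the motifs, and vice versa.
"""

from __future__ import annotations

from typing import Any

import numpy as np

from . import backgrounds as bg
from .alphabet import Alphabet, dna
from .config import RunConfig
from .errors import ConfigurationError
from .grammar import Grammar, build_grammar
from .motifs import (
    MotifSet,
    MotifSimSpec,
    MultimerRule,
    calibrate_concentration,
    multimerize,
    read_motifs,
    simulate_motifs,
)
from .sampler import InsertionPolicy, SimulationResult, run_simulation

__all__ = [
    "build_alphabet",
    "build_backgrounds",
    "build_motifs",
    "build_grammar_from_config",
    "build_policy",
    "run_from_config",
]


def build_alphabet(cfg: RunConfig) -> Alphabet:
    acfg = cfg.alphabet
    if acfg.letters == "ACGT" and acfg.complement is None:
        return dna(acfg.background_freqs)
    if acfg.complement is None:
        raise ConfigurationError(
            "alphabet.complement is required for non-ACGT letter sets"
        )
    return Alphabet(acfg.letters, acfg.complement, acfg.background_freqs)


def build_backgrounds(
    cfg: RunConfig, alphabet: Alphabet, rng: np.random.Generator
) -> bg.BackgroundPool:
    c = cfg.backgrounds
    if c.mode == "iid":
        return bg.simulate_iid(c.n, c.len_min, c.len_max, alphabet, rng)
    pool = bg.import_fasta(c.fasta, alphabet, c.on_invalid, rng)
    if c.mode == "fasta":
        return pool
    if c.mode == "shuffle":
        return bg.shuffle_pool(pool, rng)
    model = bg.fit_markov(
        [s for _, s in pool.records], c.markov_order, alphabet, c.pseudocount
    )
    return bg.markov_pool(model, c.n, c.len_min, c.len_max, rng)


def build_motifs(
    cfg: RunConfig, alphabet: Alphabet, rng: np.random.Generator
) -> MotifSet:
    c = cfg.motifs
    if c.mode == "simulate":
        if c.target_mean_ic is not None:
            alpha: Any = calibrate_concentration(
                c.target_mean_ic, alphabet.size
            )
        else:
            alpha = c.alpha if c.alpha is not None else 1.0
        spec = MotifSimSpec(
            n_motifs=c.n_motifs,
            len_min=c.len_min,
            len_max=c.len_max,
            alphabet=alphabet,
            alpha=alpha,
        )
        motif_set = simulate_motifs(spec, rng)
    else:
        motif_set = read_motifs(c.path, c.format, alphabet)
    for rule_cfg in cfg.multimers:
        rule = MultimerRule(
            component_ids=rule_cfg.components,
            spacings=rule_cfg.spacings,
            weights=rule_cfg.weights,
            id=rule_cfg.id,
        )
        motif_set.add(multimerize(motif_set, rule))
    return motif_set


def build_grammar_from_config(cfg: RunConfig, motif_set: MotifSet) -> Grammar:
    g = cfg.grammar
    members = g.groups
    if members is None:
        members = {"group_0": motif_set.ids}
    return build_grammar(
        members,
        group_marginal=g.group_marginal,
        group_conditional=g.group_conditional,
        motif_within_group=g.motif_within_group,
        motif_ids=motif_set.ids,
    )


def build_policy(cfg: RunConfig) -> InsertionPolicy:
    i = cfg.insertion
    count = ("fixed", i.count.n) if i.count.dist == "fixed" else ("poisson", i.count.lam)
    if i.position.dist == "gaussian":
        position = ("gaussian", i.position.mean_offset, i.position.sd)
    else:
        position = (i.position.dist,)
    return InsertionPolicy(
        count_dist=count,
        p_forward=i.p_forward,
        position_dist=position,
        overlap_policy=i.overlap.policy,
        max_tries=i.overlap.max_tries,
        boundary_policy=i.boundary,
    )


def run_from_config(
    cfg: RunConfig, seed: int | None = None
) -> tuple[SimulationResult, MotifSet, Grammar]:
    """Full end-to-end run: backgrounds, motifs, grammar, simulation.

    ``seed`` overrides the config's master seed when given.
    """
    master = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    bg_ss, motif_ss, sim_ss = ss.spawn(3)

    alphabet = build_alphabet(cfg)
    pool = build_backgrounds(cfg, alphabet, np.random.default_rng(bg_ss))
    motif_set = build_motifs(cfg, alphabet, np.random.default_rng(motif_ss))
    grammar = build_grammar_from_config(cfg, motif_set)
    policy = build_policy(cfg)

    provenance = {
        "seed": master,
        "config": cfg.model_dump(),
    }
    result = run_simulation(
        pool, motif_set, grammar, policy, cfg.n_sequences, sim_ss,
        provenance=provenance,
    )
    return result, motif_set, grammar
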
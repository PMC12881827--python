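"""Group-based soft co-occurrence grammar.

Motifs are organized into groups (a motif may belong to several). Within a
simulated sequence, the group of the first inserted instance is drawn from
the group marginal distribution; each subsequent group is drawn conditioned
on the previously selected group (a first-order chain). The motif itself is
then drawn from the within-group motif distribution. Motifs sharing a group
therefore co-occur in the same sequence more often than motifs in disjoint
groups whenever the group chain favors self-transitions — a soft syntax,
in contrast to the hard fixed-spacing syntax of multimers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["Grammar", "build_grammar", "sample_groups",
           "sample_motif_from_group", "implied_cooccurrence"]

_SUM_TOL = 1e-6


def _check_prob_vector(v: np.ndarray, what: str, n: int) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (n,):
        raise ConfigurationError(f"{what}: expected length {n}, got {v.size}")
    if (v < 0).any():
        raise ConfigurationError(f"{what}: negative entries")
    if abs(v.sum() - 1.0) > _SUM_TOL:
        raise ConfigurationError(f"{what}: sums to {v.sum():.6f}, not 1")
    return v


@dataclass
class Grammar:
    """Validated co-occurrence grammar.

    ``group_ids`` fixes group order; ``group_marginal`` and each row of
    ``group_conditional`` are distributions over that order;
    ``motif_within_group[g]`` is a distribution over ``group_members[g]``.
    """

    group_ids: list[str]
    group_members: dict[str, list[str]]
    group_marginal: np.ndarray
    group_conditional: np.ndarray
    motif_within_group: dict[str, np.ndarray]

    @property
    def motif_ids(self) -> list[str]:
        """All motif ids, ordered by first appearance across groups."""
        seen: dict[str, None] = {}
        for g in self.group_ids:
            for m in self.group_members[g]:
                seen.setdefault(m)
        return list(seen)

    def groups_of(self, motif_id: str) -> list[str]:
        return [g for g in self.group_ids if motif_id in self.group_members[g]]

    def share_group(self, a: str, b: str) -> bool:
        return bool(set(self.groups_of(a)) & set(self.groups_of(b)))


def build_grammar(
    members: dict[str, list[str]],
    group_marginal: np.ndarray | list[float] | None = None,
    group_conditional: np.ndarray | list[list[float]] | None = None,
    motif_within_group: dict[str, list[float]] | None = None,
    motif_ids: list[str] | None = None,
) -> Grammar:
    """Build and validate a grammar; missing distributions default to uniform.

    Parameters
    ----------
    members
        Mapping group id -> ordered list of member motif ids (nonempty).
    group_marginal, group_conditional, motif_within_group
        Optional probability tables; uniform when omitted.
    motif_ids
        When given, every referenced motif id must be in this list (used to
        cross-check against a MotifSet).
    """
    if not members:
        raise ConfigurationError("grammar needs at least one group")
    group_ids = list(members)
    G = len(group_ids)
    for g, mids in members.items():
        if not mids:
            raise ConfigurationError(f"group {g!r} is empty")
        if len(set(mids)) != len(mids):
            raise ConfigurationError(f"group {g!r} lists a motif twice")
        if motif_ids is not None:
            unknown = [m for m in mids if m not in motif_ids]
            if unknown:
                raise ConfigurationError(
                    f"group {g!r} references unknown motif ids {unknown}"
                )

    if group_marginal is None:
        marginal = np.full(G, 1.0 / G)
    else:
        marginal = _check_prob_vector(np.asarray(group_marginal), "group_marginal", G)

    if group_conditional is None:
        conditional = np.full((G, G), 1.0 / G)
    else:
        conditional = np.asarray(group_conditional, dtype=float)
        if conditional.shape != (G, G):
            raise ConfigurationError(
                f"group_conditional: expected shape ({G}, {G}), got "
                f"{conditional.shape}"
            )
        for i, g in enumerate(group_ids):
            _check_prob_vector(conditional[i], f"group_conditional row {g!r}", G)

    within: dict[str, np.ndarray] = {}
    for g in group_ids:
        n = len(members[g])
        if motif_within_group is not None and g in motif_within_group:
            within[g] = _check_prob_vector(
                np.asarray(motif_within_group[g]), f"motif_within_group[{g!r}]", n
            )
        else:
            within[g] = np.full(n, 1.0 / n)

    return Grammar(group_ids, {g: list(m) for g, m in members.items()},
                   marginal, conditional, within)


def sample_groups(
    grammar: Grammar, k: int, rng: np.random.Generator
) -> list[str]:
    """Draw a length-k group chain: marginal first, then conditional steps."""
    if k < 0:
        raise ConfigurationError(f"chain length must be >= 0, got {k}")
    chain: list[str] = []
    prev: int | None = None
    for _ in range(k):
        p = grammar.group_marginal if prev is None else grammar.group_conditional[prev]
        prev = int(rng.choice(len(grammar.group_ids), p=p))
        chain.append(grammar.group_ids[prev])
    return chain


def sample_motif_from_group(
    grammar: Grammar, group: str, rng: np.random.Generator
) -> str:
    """Draw a motif id from the group's within-group distribution."""
    if group not in grammar.group_members:
        raise ConfigurationError(f"unknown group {group!r}")
    mids = grammar.group_members[group]
    return mids[int(rng.choice(len(mids), p=grammar.motif_within_group[group]))]


def implied_cooccurrence(grammar: Grammar) -> dict[str, pd.DataFrame]:
    """Analytic co-occurrence tables implied by the grammar.

    Returns four labelled tables:

    ``group_conditional``
        P(next group | previous group), as configured.
    ``motif_marginal``
        First-draw motif probability m(a) = sum_g P(g) P(a|g).
    ``motif_joint``
        Joint probability of consecutive motif draws,
        J(a, b) = sum_{g,h} P(g) P(a|g) P(h|g) P(b|h); sums to 1.
    ``motif_conditional``
        C(b|a) = J(a, b) / sum_b J(a, b); rows sum to 1 where motif ``a``
        is reachable as a first draw.
    """
    motif_ids = grammar.motif_ids
    M, G = len(motif_ids), len(grammar.group_ids)
    midx = {m: i for i, m in enumerate(motif_ids)}

    # emit[g, a] = P(motif a | group g)
    emit = np.zeros((G, M))
    for gi, g in enumerate(grammar.group_ids):
        for m, p in zip(grammar.group_members[g], grammar.motif_within_group[g]):
            emit[gi, midx[m]] += p

    marg = grammar.group_marginal
    cond = grammar.group_conditional
    motif_marginal = marg @ emit
    joint = emit.T @ (marg[:, None] * cond) @ emit
    row_sums = joint.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        motif_conditional = np.where(
            row_sums[:, None] > 0, joint / row_sums[:, None], 0.0
        )

    gids = grammar.group_ids
    return {
        "group_conditional": pd.DataFrame(cond, index=gids, columns=gids),
        "motif_marginal": pd.DataFrame(
            motif_marginal[None, :], index=["probability"], columns=motif_ids
        ),
        "motif_joint": pd.DataFrame(joint, index=motif_ids, columns=motif_ids),
        "motif_conditional": pd.DataFrame(
            motif_conditional, index=motif_ids, columns=motif_ids
        ),
    }
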
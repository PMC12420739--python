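"""Pathway analysis of simulated profiles: ORA and pre-ranked GSEA.

ORA converts each metabolite z-score to a p-value with the standard-normal
survival function (1 - CDF), thresholds at alpha to obtain the
differentially-abundant (DA) set — deliberately without multiple-testing
correction, to preserve a minimal amount of signal — and tests each pathway
with a right-tailed Fisher's exact test against the exchangeable background.
A pathway is testable only if it contains at least ``min_hits`` DA
metabolites (default 3).

Pre-ranked GSEA ranks metabolites by signed or absolute z-score and computes
the weighted Kolmogorov-Smirnov enrichment score; significance comes from
permuting metabolite labels over the ranked scores (default 1000
permutations), one-sided within the observed sign.

Note the survival function is applied to signed z, so only metabolites that
*increase* in the medium can become DA; pass ``da_stat="abs"`` to threshold
|z| instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import MetabolitePathwaySets
from .simulate import ZScoreProfile

__all__ = [
    "RankedList",
    "PathwayEnrichment",
    "EnrichmentResult",
    "zscore_to_pvalue",
    "fisher_right_tail",
    "run_ora",
    "enrichment_score",
    "run_gsea",
    "ORA",
    "GSEA_SIGNED",
    "GSEA_ABSOLUTE",
]

ORA = "ora"
GSEA_SIGNED = "gsea_signed"
GSEA_ABSOLUTE = "gsea_absolute"


@dataclass(frozen=True)
class RankedList:
    """Metabolites sorted by score, descending; ties broken by id."""

    ids: tuple[str, ...]
    scores: tuple[float, ...]
    mode: str  # "signed" | "absolute"

    @classmethod
    def from_profile(cls, profile: ZScoreProfile, mode: str) -> "RankedList":
        if mode not in ("signed", "absolute"):
            raise ValueError(f"unknown ranking mode {mode!r}")
        items = [
            (z if mode == "signed" else abs(z), met)
            for met, z in profile.zscores.items()
        ]
        items.sort(key=lambda t: (-t[0], t[1]))
        return cls(
            ids=tuple(met for _, met in items),
            scores=tuple(score for score, _ in items),
            mode=mode,
        )


@dataclass(frozen=True)
class PathwayEnrichment:
    testable: bool
    p_value: float | None = None
    es: float | None = None
    n_hits: int = 0


@dataclass(frozen=True)
class EnrichmentResult:
    method: str
    scenario: str
    per_pathway: dict[str, PathwayEnrichment] = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> frozenset[str]:
        return frozenset(
            p for p, rec in self.per_pathway.items()
            if rec.testable and rec.p_value is not None and rec.p_value <= alpha
        )


def zscore_to_pvalue(z: float) -> float:
    """Standard-normal survival function: p = 1 - Phi(z)."""
    return float(stats.norm.sf(z))


def fisher_right_tail(k, K: int, n: int, N: int):
    """Right tail of the hypergeometric: P(X >= k) drawing n from N with K marked.

    This is the one-sided ("greater") Fisher's exact test for a 2x2
    contingency table with margins (K, N-K) x (n, N-n).  ``k`` may be a
    scalar or an array of counts.
    """
    k_arr = np.asarray(k)
    if not (
        np.all(k_arr >= 0) and np.all(k_arr <= min(K, n)) and K <= N and n <= N
    ):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    p = stats.hypergeom.sf(k_arr - 1, N, K, n)
    return float(p) if np.isscalar(k) else p


def run_ora(
    profile: ZScoreProfile,
    sets: MetabolitePathwaySets,
    background: frozenset[str],
    alpha_da: float = 0.05,
    min_hits: int = 3,
    da_stat: str = "signed",
) -> EnrichmentResult:
    """Over-representation analysis of one profile against the pathway sets.

    DA metabolites are those with survival-function p <= ``alpha_da``
    (uncorrected).  For each pathway the 2x2 table is built inside the
    background: K = pathway ∩ background, k = pathway ∩ DA, n = |DA|,
    N = |background|; a pathway with fewer than ``min_hits`` DA members is
    reported non-testable.
    """
    if not background:
        raise ValueError("empty background")
    if da_stat not in ("signed", "abs"):
        raise ValueError(f"unknown da_stat {da_stat!r}")
    da = frozenset(
        met
        for met, z in profile.zscores.items()
        if zscore_to_pvalue(abs(z) if da_stat == "abs" else z) <= alpha_da
    )
    N, n = len(background), len(da & background)
    per_pathway: dict[str, PathwayEnrichment] = {}
    for pid, members in sets.items():
        in_bg = members & background
        k = len(in_bg & da)
        if k < min_hits:
            per_pathway[pid] = PathwayEnrichment(testable=False, n_hits=k)
            continue
        p = fisher_right_tail(k, len(in_bg), n, N)
        per_pathway[pid] = PathwayEnrichment(testable=True, p_value=p, n_hits=k)
    return EnrichmentResult(method=ORA, scenario=profile.scenario,
                            per_pathway=per_pathway)


def _es_from_hits(
    scores: np.ndarray, hit_mask: np.ndarray, weight_exponent: float
) -> tuple[float, int]:
    """Weighted KS running sum; returns (es at maximal |deviation|, position)."""
    n = scores.size
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("hit set must be a non-empty proper subset")
    w = np.abs(scores) ** weight_exponent
    hit_w = np.where(hit_mask, w, 0.0)
    total = hit_w.sum()
    if total > 0:
        inc = hit_w / total
    else:  # all hit scores zero: fall back to equal weights
        inc = np.where(hit_mask, 1.0 / n_hits, 0.0)
    dec = np.where(hit_mask, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(inc - dec)
    pos = int(np.argmax(np.abs(running)))
    # float accumulation can overshoot the mathematical range by ~1 ulp
    return float(np.clip(running[pos], -1.0, 1.0)), pos


def enrichment_score(
    ranked: RankedList,
    pathway_set: frozenset[str],
    weight_exponent: float = 1.0,
) -> tuple[float, int]:
    """Pre-ranked GSEA enrichment score of ``pathway_set`` in ``ranked``.

    Walking down the ranked list, members ("hits") increment the running sum
    by |score|^weight / sum over hits of |score|^weight and non-members
    decrement it by 1/(N - N_hits); the ES is the running-sum value of
    maximal absolute deviation.  ES lies in [-1, 1].
    """
    hit_mask = np.array([m in pathway_set for m in ranked.ids], dtype=bool)
    return _es_from_hits(np.asarray(ranked.scores), hit_mask, weight_exponent)


def run_gsea(
    profile: ZScoreProfile,
    sets: MetabolitePathwaySets,
    mode: str = "absolute",
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> EnrichmentResult:
    """Pre-ranked GSEA of one profile against the pathway sets.

    The permutation p-value shuffles metabolite labels over the fixed ranked
    scores (equivalently: redraws the hit positions), counts permuted scores
    at least as extreme as the observed one within its sign, normalises by
    the number of same-sign permutations, and applies a +1 pseudo-count:
    p = (1 + extreme) / (1 + same_sign).  Pathways with no ranked member are
    non-testable.
    """
    if not profile.zscores:
        raise ValueError("empty profile")
    ranked = RankedList.from_profile(profile, mode)
    scores = np.asarray(ranked.scores)
    n = scores.size
    rng = np.random.default_rng(seed)
    per_pathway: dict[str, PathwayEnrichment] = {}
    null_cache: dict[int, np.ndarray] = {}
    for pid, members in sorted(sets.items()):
        n_hits = len(members.intersection(ranked.ids))
        if n_hits == 0:
            per_pathway[pid] = PathwayEnrichment(testable=False, n_hits=0)
            continue
        if n_hits == n:
            raise ValueError(
                f"pathway {pid!r} covers the whole ranked list; the KS "
                "miss penalty is undefined"
            )
        es, _ = enrichment_score(ranked, members, weight_exponent)
        if n_hits not in null_cache:
            null = np.empty(n_perm)
            mask = np.zeros(n, dtype=bool)
            for i in range(n_perm):
                mask[:] = False
                mask[rng.choice(n, size=n_hits, replace=False)] = True
                null[i], _ = _es_from_hits(scores, mask, weight_exponent)
            null_cache[n_hits] = null
        null = null_cache[n_hits]
        # one-sided within the observed sign, normalised by the same-sign
        # permutation count (the classical GSEA convention; normalising by
        # all permutations would leave sign-conditional p-values running at
        # twice their nominal level under the null)
        if es >= 0:
            extreme = int((null >= es).sum())
            same_sign = int((null >= 0).sum())
        else:
            extreme = int((null <= es).sum())
            same_sign = int((null < 0).sum())
        p = (1.0 + extreme) / (1.0 + same_sign)
        per_pathway[pid] = PathwayEnrichment(
            testable=True, p_value=p, es=es, n_hits=n_hits
        )
    method = GSEA_ABSOLUTE if mode == "absolute" else GSEA_SIGNED
    return EnrichmentResult(method=method, scenario=profile.scenario,
                            per_pathway=per_pathway)
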
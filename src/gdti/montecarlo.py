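"""Monte-Carlo handling of missing genotypes in pedigrees.

Missing marker genotypes are imputed by sampling from the exact conditional
distribution ``P(G_m | G_o)`` under a simple population-genetic model:
founders in Hardy-Weinberg equilibrium at M1 frequency ``p``, Mendelian
transmission, and genotypes independent of phenotype.  (Conditioning only on
genotypes matches the usual gene-counting null model; under an alternative
hypothesis with ascertained families it is an approximation.)

Pedigree likelihoods are computed by variable elimination over the genotype
factor graph (Elston-Stewart peeling generalised to arbitrary, possibly
looped, pedigrees).  Sampling uses an exact-enumeration fast path when the
number of untyped members is small (at most :data:`ENUM_MISSING_CAP`) and
otherwise falls back to exact chain-rule sampling, drawing each missing
genotype in turn from its conditional given the evidence and the draws made
so far.

The MCGDTI and MCGDT-ME statistics replace each pedigree's score and
information components with averages over ``K`` such draws; with no missing
genotypes they reduce exactly to GDTI and GDT-ME.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .association import (
    AssociationResults,
    ScoreComponents,
    chi2_quadratic_form,
    normal_ratio_statistic,
    pedigree_components,
)
from .pedigree import MarkerGenotype, Pedigree, PedigreeSet

__all__ = [
    "MCConfig",
    "GenotypeObservation",
    "estimate_allele_frequency",
    "peel_likelihood",
    "enumerate_completions",
    "sample_missing",
    "mc_components",
    "mcgdti_test",
    "mcgdt_me_test",
    "MCGDTI",
    "MCGDTME",
]

# exact-enumeration sampling is used while 3**n_missing stays at or below this
ENUM_MISSING_CAP = 3**8

_COUNT_TO_GENOTYPE = (
    MarkerGenotype(2, 2),
    MarkerGenotype(1, 2),
    MarkerGenotype(1, 1),
)


def transmission_matrix() -> np.ndarray:
    """P(child M1 count | father count, mother count), shape (3, 3, 3)."""
    t = np.empty((3, 3, 3))
    for gf in range(3):
        for gm in range(3):
            pf, pm = gf / 2.0, gm / 2.0
            t[gf, gm, 0] = (1 - pf) * (1 - pm)
            t[gf, gm, 1] = pf * (1 - pm) + (1 - pf) * pm
            t[gf, gm, 2] = pf * pm
    return t


_T3 = transmission_matrix()


def founder_prior(p: float) -> np.ndarray:
    """HWE genotype-count prior [(1-p)^2, 2p(1-p), p^2] at M1 frequency p."""
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


@dataclass(frozen=True)
class MCConfig:
    """Configuration of the Monte-Carlo sampling scheme.

    ``k`` draws are taken per pedigree (default 50).  ``freq_mode`` selects
    the M1 frequency used by the sampler: ``"true"`` takes the supplied
    ``allele_freq``, ``"founders"`` estimates it from typed founders and
    ``"all_individuals"`` from every typed member.
    """

    k: int = 50
    seed: int = 0
    allele_freq: float | None = None
    freq_mode: str = "founders"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"MC size k must be >= 1, got {self.k}")
        if self.freq_mode not in ("true", "founders", "all_individuals"):
            raise ValueError(f"unknown freq_mode {self.freq_mode!r}")
        if self.freq_mode == "true":
            if self.allele_freq is None or not 0.0 < self.allele_freq < 1.0:
                raise ValueError(
                    "freq_mode='true' requires allele_freq in (0, 1)"
                )


@dataclass(frozen=True)
class GenotypeObservation:
    """Partition of a pedigree's members into observed and missing genotypes."""

    observed: dict[str, MarkerGenotype]
    missing_ids: frozenset[str]

    @classmethod
    def from_pedigree(cls, ped: Pedigree) -> "GenotypeObservation":
        return cls(
            observed={
                m.iid: m.genotype for m in ped if m.genotype is not None
            },
            missing_ids=frozenset(m.iid for m in ped if m.genotype is None),
        )

    def validate(self, ped: Pedigree) -> None:
        ids = set(self.observed) | set(self.missing_ids)
        members = {m.iid for m in ped}
        if ids != members or set(self.observed) & set(self.missing_ids):
            raise ValueError(
                "observed and missing ids must partition the pedigree members"
            )


def estimate_allele_frequency(
    peds: PedigreeSet | Iterable[Pedigree],
    mode: str = "founders",
    value: float | None = None,
) -> float:
    """M1 allele frequency by gene counting.

    ``mode='founders'`` counts alleles of typed founders, ``'all_individuals'``
    of every typed member, ``'true'`` returns the supplied ``value``.  A
    degenerate estimate (0 or 1) or the absence of typed individuals of the
    requested class is an error.
    """
    if mode == "true":
        if value is None or not 0.0 < value < 1.0:
            raise ValueError("mode='true' requires a frequency in (0, 1)")
        return float(value)
    if mode not in ("founders", "all_individuals"):
        raise ValueError(f"unknown frequency mode {mode!r}")
    m1 = total = 0
    for ped in peds:
        pool = ped.founders if mode == "founders" else ped.members
        for ind in pool:
            if ind.genotype is not None:
                m1 += ind.genotype.m1_count
                total += 2
    if total == 0:
        raise ValueError(f"no genotyped individuals in class {mode!r}")
    p = m1 / total
    if p in (0.0, 1.0):
        raise ValueError(
            f"degenerate allele frequency estimate p={p}; sampling model "
            "requires 0 < p < 1"
        )
    return p


# ---------------------------------------------------------------------------
# pedigree likelihood by variable elimination (peeling)
# ---------------------------------------------------------------------------


def _build_factors(
    ped: Pedigree, evidence: dict[int, int], p: float
) -> list[tuple[tuple[int, ...], np.ndarray]]:
    """Factor list over member indices with evidence applied by slicing."""
    prior = founder_prior(p)
    pos = {m.iid: i for i, m in enumerate(ped.members)}
    factors: list[tuple[tuple[int, ...], np.ndarray]] = []
    for i, ind in enumerate(ped.members):
        if ind.is_founder:
            arr, axes = prior, (i,)
        else:
            arr, axes = _T3, (pos[ind.father_iid], pos[ind.mother_iid], i)
        keep_axes = []
        index: list = []
        for ax, v in enumerate(axes):
            if v in evidence:
                index.append(evidence[v])
            else:
                index.append(slice(None))
                keep_axes.append(v)
        factors.append((tuple(keep_axes), np.asarray(arr[tuple(index)])))
    return factors


def _multiply(
    f1: tuple[tuple[int, ...], np.ndarray],
    f2: tuple[tuple[int, ...], np.ndarray],
) -> tuple[tuple[int, ...], np.ndarray]:
    v1, a1 = f1
    v2, a2 = f2
    out_vars = tuple(dict.fromkeys(v1 + v2))

    def expand(vars_: tuple[int, ...], arr: np.ndarray) -> np.ndarray:
        if not vars_:
            return arr
        order = sorted(range(len(vars_)), key=lambda i: out_vars.index(vars_[i]))
        sl = tuple(slice(None) if v in vars_ else None for v in out_vars)
        return np.transpose(arr, order)[sl]

    return out_vars, expand(v1, a1) * expand(v2, a2)


def _eliminate_all(
    factors: list[tuple[tuple[int, ...], np.ndarray]]
) -> float:
    """Sum the factor product over all variables (greedy elimination order)."""
    factors = list(factors)
    while True:
        hidden = sorted({v for vars_, _ in factors for v in vars_})
        if not hidden:
            break
        # greedy: eliminate the variable whose merged factor is smallest
        best_v, best_cost = None, None
        for v in hidden:
            involved = {u for vars_, _ in factors if v in vars_ for u in vars_}
            cost = 3 ** len(involved)
            if best_cost is None or cost < best_cost:
                best_v, best_cost = v, cost
        group = [f for f in factors if best_v in f[0]]
        rest = [f for f in factors if best_v not in f[0]]
        merged = group[0]
        for f in group[1:]:
            merged = _multiply(merged, f)
        vars_, arr = merged
        axis = vars_.index(best_v)
        rest.append(
            (tuple(u for u in vars_ if u != best_v), arr.sum(axis=axis))
        )
        factors = rest
    out = 1.0
    for _, arr in factors:
        out *= float(arr)
    return out


def _evidence_from_observation(
    ped: Pedigree, obs: GenotypeObservation
) -> dict[int, int]:
    pos = {m.iid: i for i, m in enumerate(ped.members)}
    return {pos[iid]: g.m1_count for iid, g in obs.observed.items()}


def peel_likelihood(
    ped: Pedigree, obs: GenotypeObservation | None = None, p: float = 0.5
) -> float:
    """Exact probability of the observed genotypes ``P(G_o)``.

    Model: founders in HWE at M1 frequency ``p``, Mendelian transmission,
    genotypes independent of phenotype.  Mendelian-impossible observations
    return 0.  With nothing observed the likelihood is 1.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0,1), got {p}")
    if obs is None:
        obs = GenotypeObservation.from_pedigree(ped)
    else:
        obs.validate(ped)
    evidence = _evidence_from_observation(ped, obs)
    return _eliminate_all(_build_factors(ped, evidence, p))


def enumerate_completions(
    ped: Pedigree, obs: GenotypeObservation | None = None, p: float = 0.5
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """All completions of the missing genotypes with their joint weights.

    Returns ``(missing_ids, counts, weights)`` where ``counts`` has shape
    (3^m, m) giving the M1 count of each missing member per completion and
    ``weights[c] = P(G_o, completion c)`` (so ``weights.sum()`` equals the
    peeling likelihood and ``weights / weights.sum()`` is the conditional).
    """
    if obs is None:
        obs = GenotypeObservation.from_pedigree(ped)
    else:
        obs.validate(ped)
    missing = sorted(obs.missing_ids, key=[m.iid for m in ped.members].index)
    m = len(missing)
    n = ped.n
    pos = {ind.iid: i for i, ind in enumerate(ped.members)}
    counts = (
        np.indices((3,) * m).reshape(m, -1).T
        if m
        else np.zeros((1, 0), dtype=int)
    )
    g = np.empty((counts.shape[0], n), dtype=int)
    for iid, geno in obs.observed.items():
        g[:, pos[iid]] = geno.m1_count
    for col, iid in enumerate(missing):
        g[:, pos[iid]] = counts[:, col]
    prior = founder_prior(p)
    w = np.ones(counts.shape[0])
    for ind in ped.members:
        i = pos[ind.iid]
        if ind.is_founder:
            w *= prior[g[:, i]]
        else:
            w *= _T3[g[:, pos[ind.father_iid]], g[:, pos[ind.mother_iid]], g[:, i]]
    return missing, counts, w


def _rng_for_pedigree(seed: int, fid: str) -> np.random.Generator:
    """Per-pedigree substream keyed by family id, independent of ordering."""
    key = zlib.crc32(fid.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _sample_counts(
    ped: Pedigree,
    obs: GenotypeObservation,
    p: float,
    k: int,
    rng: np.random.Generator,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Draw K completions; returns (missing_ids, unique_counts, draw_counts).

    ``unique_counts`` lists each possible completion once (shape (C, m));
    ``draw_counts`` gives how many of the K draws hit each.
    """
    missing = sorted(
        obs.missing_ids, key=[m.iid for m in ped.members].index
    )
    m = len(missing)
    if m == 0:
        return missing, np.zeros((1, 0), dtype=int), np.array([k])
    if 3**m <= ENUM_MISSING_CAP:
        _, counts, w = enumerate_completions(ped, obs, p)
        total = w.sum()
        if total <= 0.0:
            raise ValueError(
                f"pedigree {ped.fid}: observed genotypes are "
                "Mendelian-impossible (P(G_o) = 0)"
            )
        return missing, counts, rng.multinomial(k, w / total)
    # chain-rule fallback: condition each missing member in turn
    if peel_likelihood(ped, obs, p) <= 0.0:
        raise ValueError(
            f"pedigree {ped.fid}: observed genotypes are Mendelian-impossible"
        )
    pos = {ind.iid: i for i, ind in enumerate(ped.members)}
    base = _evidence_from_observation(ped, obs)
    draws = np.empty((k, m), dtype=int)
    for d in range(k):
        evidence = dict(base)
        for col, iid in enumerate(missing):
            w = np.empty(3)
            for val in range(3):
                evidence[pos[iid]] = val
                w[val] = _eliminate_all(_build_factors(ped, evidence, p))
            w /= w.sum()
            g = int(rng.choice(3, p=w))
            evidence[pos[iid]] = g
            draws[d, col] = g
    uniq, draw_counts = np.unique(draws, axis=0, return_counts=True)
    return missing, uniq, draw_counts


def sample_missing(
    ped: Pedigree,
    obs: GenotypeObservation | None = None,
    cfg: MCConfig = MCConfig(allele_freq=0.5, freq_mode="true"),
    rng: np.random.Generator | None = None,
) -> list[dict[str, MarkerGenotype]]:
    """K independent draws of the missing genotypes from ``P(G_m | G_o)``.

    Each draw is a complete genotype map for the pedigree (observed genotypes
    are passed through unchanged).  Reproducible given ``cfg.seed`` when no
    explicit generator is supplied.
    """
    if obs is None:
        obs = GenotypeObservation.from_pedigree(ped)
    else:
        obs.validate(ped)
    p = _sampling_frequency(cfg, [ped])
    if rng is None:
        rng = _rng_for_pedigree(cfg.seed, ped.fid)
    missing, counts, draw_counts = _sample_counts(ped, obs, p, cfg.k, rng)
    out: list[dict[str, MarkerGenotype]] = []
    for row, times in zip(counts, draw_counts):
        completion = dict(obs.observed)
        for iid, c in zip(missing, row):
            completion[iid] = _COUNT_TO_GENOTYPE[c]
        out.extend([completion] * int(times))
    return out


def _sampling_frequency(
    cfg: MCConfig, peds: PedigreeSet | Iterable[Pedigree]
) -> float:
    if cfg.freq_mode == "true":
        return float(cfg.allele_freq)
    return estimate_allele_frequency(peds, mode=cfg.freq_mode)


def mc_components(
    ped: Pedigree,
    obs: GenotypeObservation | None = None,
    cfg: MCConfig = MCConfig(allele_freq=0.5, freq_mode="true"),
    rng: np.random.Generator | None = None,
    p: float | None = None,
    unknown_affection: str = "unaffected",
) -> ScoreComponents | None:
    """Score/information components averaged over K conditional draws.

    With no missing genotypes the conditional is degenerate and the result
    equals the complete-data components exactly, for any K.  Returns ``None``
    for pedigrees without a discordant pair.
    """
    if obs is None:
        obs = GenotypeObservation.from_pedigree(ped)
    else:
        obs.validate(ped)
    a_i = ped.n_affected(unknown_affection)
    u_i = ped.n_unaffected(unknown_affection)
    if a_i == 0 or u_i == 0:
        return None
    if not obs.missing_ids:
        return pedigree_components(ped, unknown_affection=unknown_affection)
    if p is None:
        p = _sampling_frequency(cfg, [ped])
    if rng is None:
        rng = _rng_for_pedigree(cfg.seed, ped.fid)
    missing, counts, draw_counts = _sample_counts(ped, obs, p, cfg.k, rng)
    acc = np.zeros(6)
    for row, times in zip(counts, draw_counts):
        if times == 0:
            continue
        completion = {
            iid: _COUNT_TO_GENOTYPE[c] for iid, c in zip(missing, row)
        }
        comp = pedigree_components(
            ped.with_genotypes(completion), unknown_affection=unknown_affection
        )
        acc += (times / cfg.k) * np.array(
            [comp.s, comp.d1, comp.d2, comp.i11, comp.i22, comp.i12]
        )
    return ScoreComponents(*acc)


# ---------------------------------------------------------------------------
# Monte-Carlo test statistics
# ---------------------------------------------------------------------------


class _MCTestModel:
    def __init__(
        self,
        data: PedigreeSet,
        config: MCConfig = MCConfig(),
        unknown_affection: str = "unaffected",
    ):
        self.data = data
        self.config = config
        self.unknown_affection = unknown_affection

    def _all_components(self) -> tuple[list[ScoreComponents], int, float]:
        cfg = self.config
        p = _sampling_frequency(cfg, self.data)
        comps: list[ScoreComponents] = []
        skipped = 0
        for ped in self.data:
            comp = mc_components(
                ped,
                cfg=cfg,
                rng=_rng_for_pedigree(cfg.seed, ped.fid),
                p=p,
                unknown_affection=self.unknown_affection,
            )
            if comp is None:
                skipped += 1
            else:
                comps.append(comp)
        return comps, skipped, p

    def _extras(self, p: float) -> dict:
        return {"K": self.config.k, "freq_mode": self.config.freq_mode,
                "p_hat": p}


class MCGDTI(_MCTestModel):
    """GDTI on Monte-Carlo-averaged components (incomplete pedigree data)."""

    test_name = "MCGDTI"

    def fit(self) -> AssociationResults:
        comps, skipped, p = self._all_components()
        d_sum = np.zeros(2)
        info_sum = np.zeros((2, 2))
        for c in comps:
            d_sum += (c.d1, c.d2)
            info_sum += c.information
        stat, df, pval, flags = chi2_quadratic_form(d_sum, info_sum)
        return AssociationResults(
            test=self.test_name,
            statistic=stat,
            p_value=pval,
            df=df,
            n_pedigrees_used=len(comps),
            n_pedigrees_skipped=skipped,
            flags=flags,
            extras=self._extras(p),
        )


class MCGDTME(_MCTestModel):
    """GDT-ME on Monte-Carlo-averaged pedigree scores."""

    test_name = "MCGDT-ME"

    def fit(self) -> AssociationResults:
        comps, skipped, p = self._all_components()
        s = np.array([c.s for c in comps])
        stat, pval, flags = normal_ratio_statistic(s)
        return AssociationResults(
            test=self.test_name,
            statistic=stat,
            p_value=pval,
            df=None,
            n_pedigrees_used=len(comps),
            n_pedigrees_skipped=skipped,
            flags=flags,
            extras=self._extras(p),
        )


def mcgdti_test(
    peds: PedigreeSet,
    cfg: MCConfig = MCConfig(),
    unknown_affection: str = "unaffected",
) -> AssociationResults:
    """MCGDTI statistic with a chi-square (df 2) p-value."""
    return MCGDTI(peds, cfg, unknown_affection).fit()


def mcgdt_me_test(
    peds: PedigreeSet,
    cfg: MCConfig = MCConfig(),
    unknown_affection: str = "unaffected",
) -> AssociationResults:
    """MCGDT-ME statistic with a two-sided normal p-value."""
    return MCGDTME(peds, cfg, unknown_affection).fit()
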
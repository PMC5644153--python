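"""Family-based association tests on complete-genotype pedigrees.

Three statistics are provided, all built from genotype differences between
discordant (affected vs unaffected) relative pairs within each pedigree:

``GDT-ME``
    Generalized disequilibrium test with a moment variance estimate.  The
    pedigree score ``S_i = (1/N_i) * sum_{j affected} sum_{k unaffected}
    (X_ij - X_ik)`` is summed over pedigrees and studentised by
    ``sqrt(sum S_i^2)``; the statistic is referred to the standard normal.

``GDT``
    The same numerator with a variance reconstructed from kinship
    coefficients under Hardy-Weinberg equilibrium,
    ``V_i = (1/N_i^2) a' C a`` with ``C_jk = 4 phi_jk p (1-p)``.  This is a
    comparator approximation: the kinship-based variance is assembled here
    from the standard recursive kinship coefficients rather than from
    observed identity-by-descent sharing.

``GDTI``
    A two-degree-of-freedom score test for association allowing genomic
    imprinting.  Each genotype score is decomposed into paternal and maternal
    allele scores (see :mod:`gdti.scoring`); the per-pedigree score vector
    ``(D_i1, D_i2)`` collects paternal and maternal contrast sums and the
    2x2 observed Fisher information is an exact combinatorial expectation
    over all ways of choosing ``A_i`` affected members out of ``N_i``.  The
    information is evaluated either by explicit subset enumeration (the
    reference route) or by an algebraically equivalent closed form based on
    the sampling-without-replacement variance of a subset sum (the fast
    route); the two agree to floating-point precision.

Pedigrees without at least one affected and one unaffected member carry no
discordant pairs and are skipped (and counted as skipped in the results).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping

import numpy as np
from scipy import stats

from .pedigree import Pedigree, PedigreeSet
from .scoring import AlleleScores, decompose_scores, genotype_score

__all__ = [
    "ScoreComponents",
    "AssociationResults",
    "KinshipMatrix",
    "pedigree_score_s",
    "pedigree_scores_gdti",
    "information_enumeration",
    "information_closed_form",
    "kinship_matrix",
    "gdt_me_test",
    "gdt_test",
    "gdti_test",
    "GDTME",
    "GDT",
    "GDTI",
    "ENUMERATION_CAP",
]

ENUMERATION_CAP = 10**6  # largest C(N_i, A_i) enumerated exactly

# rank tolerance (relative to the largest eigenvalue) for the summed
# information matrix in the quadratic form
_RANK_RTOL = 1e-10


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreComponents:
    """Per-pedigree score and information contributions.

    ``d1 + d2 == s`` exactly (paternal plus maternal contrasts reassemble the
    genotype-score contrast), and the 2x2 information block
    ``[[i11, i12], [i12, i22]]`` is symmetric positive semidefinite.
    """

    s: float
    d1: float
    d2: float
    i11: float
    i22: float
    i12: float

    @property
    def information(self) -> np.ndarray:
        return np.array([[self.i11, self.i12], [self.i12, self.i22]])


@dataclass
class AssociationResults:
    """Outcome of one association test on a pedigree set.

    ``df`` is ``None`` for statistics referred to the standard normal and the
    chi-square degrees of freedom otherwise.  ``flags`` records boundary
    conditions (degenerate variance, singular information).
    """

    test: str
    statistic: float
    p_value: float
    df: int | None = None
    n_pedigrees_used: int = 0
    n_pedigrees_skipped: int = 0
    flags: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @property
    def reference(self) -> str:
        return "normal" if self.df is None else f"chi2({self.df})"

    def summary(self) -> str:
        lines = [
            f"{self.test} association test",
            "-" * 40,
            f"statistic        {self.statistic:12.6f}",
            f"reference        {self.reference:>12s}",
            f"p-value          {self.p_value:12.6g}",
            f"pedigrees used   {self.n_pedigrees_used:12d}",
            f"pedigrees skipped{self.n_pedigrees_skipped:12d}",
        ]
        for key, val in self.extras.items():
            lines.append(f"{key:<17s}{val!r:>12s}" if isinstance(val, str)
                         else f"{key:<17s}{val:12.6g}")
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)

    def to_row(self, marker: str = "marker") -> dict:
        row = {
            "marker": marker,
            "test": self.test,
            "statistic": self.statistic,
            "df": "" if self.df is None else self.df,
            "p_value": self.p_value,
            "n_used": self.n_pedigrees_used,
            "n_skipped": self.n_pedigrees_skipped,
        }
        row.update(self.extras)
        return row


# ---------------------------------------------------------------------------
# array kernels (shared with the vectorised simulation engine)
# ---------------------------------------------------------------------------


def contrast_sums(x: np.ndarray, aff: np.ndarray) -> np.ndarray:
    """Per-member discordant-pair contrast ``c_j = sum_{k unaffected} (x_j - x_k)``.

    ``x`` holds scores with shape (..., N); ``aff`` is a boolean affection
    mask of the same shape.  The unaffected members always have zero total:
    ``sum_{k unaffected} c_k = 0``.
    """
    un = ~aff
    u = un.sum(axis=-1, keepdims=True)
    return u * x - (x * un).sum(axis=-1, keepdims=True)


def components_closed_form(
    xp: np.ndarray, xm: np.ndarray, aff: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorised scores and information, closed form.

    Rows must satisfy ``1 <= A < N``.  The first information term — the
    average over all size-A subsets ``s`` of ``[sum_{j in s} c_j]^2`` — is
    computed as ``Var + (A*cbar)^2`` where ``Var`` is the exact
    without-replacement variance ``A(N-A)/(N-1) * (1/N) sum_j (c_j-cbar)^2``
    of a subset sum, instead of enumerating the C(N, A) subsets.
    """
    n = aff.shape[-1]
    a = aff.sum(axis=-1)
    u = n - a
    cp = contrast_sums(xp, aff)
    cm = contrast_sums(xm, aff)
    pp = (cp * aff).sum(axis=-1)
    pm = (cm * aff).sum(axis=-1)
    cbar_p = cp.mean(axis=-1)
    cbar_m = cm.mean(axis=-1)
    dev_p = cp - cbar_p[..., None]
    dev_m = cm - cbar_m[..., None]
    hyp = a * (n - a) / (n - 1) if n > 1 else np.zeros_like(a, dtype=float)
    var_p = hyp * (dev_p**2).mean(axis=-1)
    var_m = hyp * (dev_m**2).mean(axis=-1)
    cov = hyp * (dev_p * dev_m).mean(axis=-1)
    second = (a / (u * n)) ** 2
    i11 = (var_p + (a * cbar_p) ** 2) / u**2 - second * pp**2
    i22 = (var_m + (a * cbar_m) ** 2) / u**2 - second * pm**2
    i12 = (cov + a**2 * cbar_p * cbar_m) / u**2 - second * pp * pm
    return {
        "s": (pp + pm) / n,
        "d1": pp / n,
        "d2": pm / n,
        "i11": i11,
        "i22": i22,
        "i12": i12,
    }


def components_enumeration(
    xp: np.ndarray, xm: np.ndarray, aff: np.ndarray
) -> dict[str, float]:
    """Scores and information by explicit enumeration of affected subsets.

    Evaluates the information formulas literally: the first term averages the
    squared subset contrast sum over all C(N, A) subsets of size A (the inner
    unaffected sum always taken over the original unaffected set).  Exact but
    exponential; serves as the reference for :func:`components_closed_form`.
    """
    xp = np.asarray(xp, dtype=float)
    xm = np.asarray(xm, dtype=float)
    aff = np.asarray(aff, dtype=bool)
    n = aff.size
    a = int(aff.sum())
    u = n - a
    if a < 1 or u < 1:
        raise ValueError("enumeration requires at least one affected and one "
                         "unaffected member")
    n_subsets = comb(n, a)
    if n_subsets > ENUMERATION_CAP:
        raise ValueError(
            f"C({n},{a}) = {n_subsets} exceeds the enumeration cap; use "
            "information_closed_form"
        )
    cp = contrast_sums(xp, aff)
    cm = contrast_sums(xm, aff)
    pp = float(cp[aff].sum())
    pm = float(cm[aff].sum())
    subsets = np.fromiter(
        (idx for s in combinations(range(n), a) for idx in s), dtype=np.intp
    ).reshape(n_subsets, a)
    tp = cp[subsets].sum(axis=1)
    tm = cm[subsets].sum(axis=1)
    second = (a / (u * n)) ** 2
    return {
        "s": (pp + pm) / n,
        "d1": pp / n,
        "d2": pm / n,
        "i11": float((tp**2).mean() / u**2 - second * pp**2),
        "i22": float((tm**2).mean() / u**2 - second * pm**2),
        "i12": float((tp * tm).mean() / u**2 - second * pp * pm),
    }


# ---------------------------------------------------------------------------
# object-level operations
# ---------------------------------------------------------------------------


def _affection_mask(
    ped: Pedigree, ids: list[str], unknown_affection: str
) -> np.ndarray:
    resolved = ped.resolved_affection(unknown_affection)
    return np.array([bool(resolved.get(i, 0)) for i in ids], dtype=bool)


def _score_arrays(
    ped: Pedigree, scores: Mapping[str, AlleleScores]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    ids = [m.iid for m in ped]
    xp = np.array([scores[i].xp for i in ids])
    xm = np.array([scores[i].xm for i in ids])
    return ids, xp, xm


def pedigree_score_s(
    ped: Pedigree,
    scores: Mapping[str, float] | None = None,
    unknown_affection: str = "unaffected",
) -> float | None:
    """GDT-ME pedigree score S_i, or None if the pedigree has no discordant pair.

    ``scores`` maps iid to genotype score X; by default X is computed from the
    stored genotypes of the typed members (untyped members are dropped).
    Members whose affection resolves to unknown-excluded are dropped as well.
    """
    if scores is None:
        scores = {
            m.iid: genotype_score(m.genotype)
            for m in ped
            if m.genotype is not None
        }
    resolved = ped.resolved_affection(unknown_affection)
    ids = [i for i in scores if i in resolved]
    if not ids:
        return None
    x = np.array([scores[i] for i in ids], dtype=float)
    aff = np.array([bool(resolved[i]) for i in ids])
    a = int(aff.sum())
    if a == 0 or a == len(ids):
        return None
    c = contrast_sums(x, aff)
    return float(c[aff].sum() / len(ids))


def pedigree_scores_gdti(
    ped: Pedigree,
    scores: Mapping[str, AlleleScores] | None = None,
    unknown_affection: str = "unaffected",
) -> tuple[float, float]:
    """Paternal and maternal score sums (D_i1, D_i2) for a fully typed pedigree."""
    if scores is None:
        scores = decompose_scores(ped)
    ids, xp, xm = _score_arrays(ped, scores)
    aff = _affection_mask(ped, ids, unknown_affection)
    comp = components_closed_form(xp, xm, aff)
    return float(comp["d1"]), float(comp["d2"])


def information_enumeration(
    ped: Pedigree,
    scores: Mapping[str, AlleleScores] | None = None,
    unknown_affection: str = "unaffected",
) -> tuple[float, float, float]:
    """(I_i11, I_i22, I_i12) by subset enumeration (reference route)."""
    if scores is None:
        scores = decompose_scores(ped)
    ids, xp, xm = _score_arrays(ped, scores)
    aff = _affection_mask(ped, ids, unknown_affection)
    comp = components_enumeration(xp, xm, aff)
    return comp["i11"], comp["i22"], comp["i12"]


def information_closed_form(
    ped: Pedigree,
    scores: Mapping[str, AlleleScores] | None = None,
    unknown_affection: str = "unaffected",
) -> tuple[float, float, float]:
    """(I_i11, I_i22, I_i12) by the O(N) closed form (production route)."""
    if scores is None:
        scores = decompose_scores(ped)
    ids, xp, xm = _score_arrays(ped, scores)
    aff = _affection_mask(ped, ids, unknown_affection)
    if ped.n == 1:
        return 0.0, 0.0, 0.0
    comp = components_closed_form(xp, xm, aff)
    return float(comp["i11"]), float(comp["i22"]), float(comp["i12"])


def pedigree_components(
    ped: Pedigree,
    scores: Mapping[str, AlleleScores] | None = None,
    unknown_affection: str = "unaffected",
) -> ScoreComponents | None:
    """All score/information components for one pedigree, or None if skipped."""
    if scores is None:
        scores = decompose_scores(ped)
    ids, xp, xm = _score_arrays(ped, scores)
    aff = _affection_mask(ped, ids, unknown_affection)
    a = int(aff.sum())
    if a == 0 or a == len(ids):
        return None
    comp = components_closed_form(xp, xm, aff)
    return ScoreComponents(**{k: float(v) for k, v in comp.items()})


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KinshipMatrix:
    """Kinship coefficients phi_jk for one pedigree, indexed by iid pairs."""

    ids: tuple[str, ...]
    phi: np.ndarray

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.phi[i, j])


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Recursive kinship coefficients, founders assumed unrelated and non-inbred.

    phi_jj = 1/2 + phi_fm / 2 (f, m the parents of j; 0 for founders) and
    phi_jk = (phi_fk + phi_mk) / 2 for k processed before j in generation
    order.  Rows/columns follow the pedigree's stored member order.
    """
    order = ped.topological_order()
    pos = {ind.iid: i for i, ind in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for j, ind in enumerate(order):
        if ind.is_founder:
            phi[j, j] = 0.5
            continue
        f, m = pos[ind.father_iid], pos[ind.mother_iid]
        phi[j, j] = 0.5 + 0.5 * phi[f, m]
        for k in range(j):
            phi[j, k] = phi[k, j] = 0.5 * (phi[f, k] + phi[m, k])
    # re-order to the stored member order
    ids = [m.iid for m in ped]
    perm = [pos[i] for i in ids]
    return KinshipMatrix(tuple(ids), phi[np.ix_(perm, perm)])


# ---------------------------------------------------------------------------
# statistic assembly
# ---------------------------------------------------------------------------


def normal_ratio_statistic(
    scores: np.ndarray, variances: np.ndarray | None = None
) -> tuple[float, float, list[str]]:
    """``sum S_i / sqrt(sum V_i)`` with a two-sided normal p-value.

    ``variances=None`` uses the moment estimate ``V_i = S_i^2``.  A zero
    denominator yields statistic 0, p-value 1 and a ``degenerate_variance``
    flag.
    """
    num = float(np.sum(scores))
    den = float(np.sum(scores**2 if variances is None else variances))
    if den <= 0.0:
        return 0.0, 1.0, ["degenerate_variance"]
    z = num / np.sqrt(den)
    return z, float(2.0 * stats.norm.sf(abs(z))), []


def chi2_quadratic_form(
    d: np.ndarray, info: np.ndarray
) -> tuple[float, int, float, list[str]]:
    """GDTI quadratic form ``d' info^{-1} d`` with rank-adjusted chi-square df.

    A singular summed information matrix is inverted by Moore-Penrose
    pseudo-inverse with the degrees of freedom reduced to the matrix rank
    (flagged ``singular_information``); rank 0 yields statistic 0, p 1.
    """
    d = np.asarray(d, dtype=float)
    info = np.asarray(info, dtype=float)
    eig = np.linalg.eigvalsh(info)
    tol = max(eig.max(), 0.0) * _RANK_RTOL
    rank = int((eig > tol).sum())
    if rank == 0:
        return 0.0, 0, 1.0, ["rank_zero_information"]
    flags: list[str] = []
    if rank < info.shape[0]:
        flags.append("singular_information")
        stat = float(d @ np.linalg.pinv(info, rcond=_RANK_RTOL) @ d)
    else:
        stat = float(d @ np.linalg.solve(info, d))
    p = float(stats.chi2.sf(stat, df=rank))
    return stat, rank, p, flags


# ---------------------------------------------------------------------------
# model classes (statsmodels-style) and functional wrappers
# ---------------------------------------------------------------------------


class _PedigreeTestModel:
    """Shared scaffolding: hold a PedigreeSet, resolve affection, fit once."""

    test_name = "?"

    def __init__(self, data: PedigreeSet, unknown_affection: str = "unaffected"):
        self.data = data
        self.unknown_affection = unknown_affection

    def fit(self) -> AssociationResults:  # pragma: no cover - abstract
        raise NotImplementedError


class GDTME(_PedigreeTestModel):
    """Generalized disequilibrium test with the moment variance estimate.

    Untyped members are dropped from the pair sums; pedigrees left without a
    discordant pair are skipped.
    """

    test_name = "GDT-ME"

    def fit(self) -> AssociationResults:
        s_values = []
        skipped = 0
        for ped in self.data:
            s = pedigree_score_s(ped, unknown_affection=self.unknown_affection)
            if s is None:
                skipped += 1
            else:
                s_values.append(s)
        stat, p, flags = normal_ratio_statistic(np.array(s_values))
        return AssociationResults(
            test=self.test_name,
            statistic=stat,
            p_value=p,
            df=None,
            n_pedigrees_used=len(s_values),
            n_pedigrees_skipped=skipped,
            flags=flags,
        )


class GDT(_PedigreeTestModel):
    """GDT with the kinship-coefficient variance under HWE.

    ``allele_freq`` is the M1 frequency p used in ``C_jk = 4 phi_jk p(1-p)``;
    if ``None`` it is estimated from the typed founders.
    """

    test_name = "GDT"

    def __init__(
        self,
        data: PedigreeSet,
        allele_freq: float | None = None,
        unknown_affection: str = "unaffected",
    ):
        super().__init__(data, unknown_affection)
        self.allele_freq = allele_freq

    def fit(self) -> AssociationResults:
        p_hat = self.allele_freq
        if p_hat is None:
            from .montecarlo import estimate_allele_frequency

            p_hat = estimate_allele_frequency(self.data, mode="founders")
        if not 0.0 < p_hat < 1.0:
            raise ValueError(f"allele frequency must be in (0,1), got {p_hat}")
        s_values, v_values = [], []
        skipped = 0
        for ped in self.data:
            resolved = ped.resolved_affection(self.unknown_affection)
            kin = kinship_matrix(ped)
            typed = [
                i for i in ped.genotyped_ids() if i in resolved
            ]
            aff = np.array([bool(resolved[i]) for i in typed])
            if aff.size == 0 or aff.all() or not aff.any():
                skipped += 1
                continue
            n_t = len(typed)
            a_i, u_i = int(aff.sum()), n_t - int(aff.sum())
            x = np.array(
                [genotype_score(ped[i].genotype) for i in typed], dtype=float
            )
            s_values.append(float(contrast_sums(x, aff)[aff].sum() / n_t))
            idx = [kin.ids.index(i) for i in typed]
            c = 4.0 * kin.phi[np.ix_(idx, idx)] * p_hat * (1.0 - p_hat)
            a_vec = np.where(aff, u_i, -a_i).astype(float)
            v_values.append(float(a_vec @ c @ a_vec) / n_t**2)
        stat, p, flags = normal_ratio_statistic(
            np.array(s_values), np.array(v_values)
        )
        return AssociationResults(
            test=self.test_name,
            statistic=stat,
            p_value=p,
            df=None,
            n_pedigrees_used=len(s_values),
            n_pedigrees_skipped=skipped,
            flags=flags,
            extras={"p_hat": p_hat},
        )


class GDTI(_PedigreeTestModel):
    """Two-df score test for association with imprinting (complete data).

    All contributing pedigrees must be fully genotyped; incomplete pedigrees
    raise, directing the caller to the Monte-Carlo variant.
    """

    test_name = "GDTI"

    def fit(self) -> AssociationResults:
        used = 0
        skipped = 0
        d_sum = np.zeros(2)
        info_sum = np.zeros((2, 2))
        for ped in self.data:
            comp = pedigree_components(
                ped, unknown_affection=self.unknown_affection
            )
            if comp is None:
                skipped += 1
                continue
            d_sum += (comp.d1, comp.d2)
            info_sum += comp.information
            used += 1
        stat, df, p, flags = chi2_quadratic_form(d_sum, info_sum)
        return AssociationResults(
            test=self.test_name,
            statistic=stat,
            p_value=p,
            df=df,
            n_pedigrees_used=used,
            n_pedigrees_skipped=skipped,
            flags=flags,
        )


def gdt_me_test(
    peds: PedigreeSet, unknown_affection: str = "unaffected"
) -> AssociationResults:
    """GDT-ME statistic and two-sided normal p-value."""
    return GDTME(peds, unknown_affection).fit()


def gdt_test(
    peds: PedigreeSet,
    allele_freq: float | None = None,
    unknown_affection: str = "unaffected",
) -> AssociationResults:
    """Kinship-variance GDT statistic and two-sided normal p-value."""
    return GDT(peds, allele_freq, unknown_affection).fit()


def gdti_test(
    peds: PedigreeSet, unknown_affection: str = "unaffected"
) -> AssociationResults:
    """GDTI score statistic with a chi-square (df 2) p-value."""
    return GDTI(peds, unknown_affection).fit()
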
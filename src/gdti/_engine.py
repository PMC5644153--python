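"""Vectorised batch kernels for the simulation experiments.

The size/power experiments evaluate the test statistics over thousands of
replicates of 90-300 pedigrees, which is impractical member-object by
member-object.  This module mirrors the object-level operations on plain
numpy arrays: pedigrees of one template are simulated, phased and scored as
rows of (batch, n_members) arrays.  Genotypes are carried as M1 allele
counts (0, 1, 2).

The array kernels share the closed-form component code with
:mod:`gdti.association`; the phase-resolution rules are re-expressed in
vector form here and are cross-checked against :func:`gdti.scoring.
decompose_scores` in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .association import components_closed_form, kinship_matrix
from .montecarlo import founder_prior, transmission_matrix
from .simulate import PedigreeTemplate

_T3 = transmission_matrix()


@dataclass(frozen=True)
class TemplateArrays:
    """Index arrays describing one pedigree template."""

    template: PedigreeTemplate
    n: int
    founder_idx: tuple[int, ...]
    # (child, father, mother) index triplets in parents-first order
    trios: tuple[tuple[int, int, int], ...]
    missing_idx: tuple[int, ...]
    typed_idx: tuple[int, ...]
    phi: np.ndarray  # kinship matrix in member order

    @classmethod
    @lru_cache(maxsize=None)
    def from_template(cls, template: PedigreeTemplate) -> "TemplateArrays":
        pos = {iid: i for i, iid in enumerate(template.iids)}
        founders = tuple(
            i for i, f in enumerate(template.fathers) if f is None
        )
        trios = tuple(
            (i, pos[f], pos[m])
            for i, (f, m) in enumerate(
                zip(template.fathers, template.mothers)
            )
            if f is not None
        )
        missing = tuple(pos[i] for i in template.missing_iids)
        typed = tuple(i for i in range(template.n) if i not in missing)
        phi = kinship_matrix(template.skeleton()).phi
        return cls(
            template=template,
            n=template.n,
            founder_idx=founders,
            trios=trios,
            missing_idx=missing,
            typed_idx=typed,
            phi=phi,
        )

    @property
    def nonfounder_idx(self) -> tuple[int, ...]:
        return tuple(t[0] for t in self.trios)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------


def drop_batch(
    ta: TemplateArrays,
    hap_freqs: np.ndarray,
    pen_matrix: np.ndarray,
    rng: np.random.Generator,
    b: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gene-drop ``b`` pedigrees of one template.

    Returns (paternal, maternal, affected): haplotype code arrays of shape
    (b, n) plus a boolean affection array.  Founders draw haplotype pairs
    i.i.d. from ``hap_freqs``; each nonfounder receives one of each parent's
    two haplotypes uniformly (complete linkage, no recombination).
    Affection is Bernoulli with penetrance ``pen_matrix[paternal D,
    maternal D]``.
    """
    n = ta.n
    pat = np.zeros((b, n), dtype=np.int8)
    mat = np.zeros((b, n), dtype=np.int8)
    nf = len(ta.founder_idx)
    draws = rng.choice(4, size=(b, nf, 2), p=hap_freqs).astype(np.int8)
    f_idx = list(ta.founder_idx)
    pat[:, f_idx] = draws[:, :, 0]
    mat[:, f_idx] = draws[:, :, 1]
    for child, father, mother in ta.trios:
        pick_f = rng.integers(0, 2, size=b, dtype=np.int8)
        pick_m = rng.integers(0, 2, size=b, dtype=np.int8)
        pat[:, child] = np.where(pick_f == 0, pat[:, father], mat[:, father])
        mat[:, child] = np.where(pick_m == 0, pat[:, mother], mat[:, mother])
    carries_d_pat = (pat % 2 == 0).astype(np.intp)
    carries_d_mat = (mat % 2 == 0).astype(np.intp)
    pen = pen_matrix[carries_d_pat, carries_d_mat]
    affected = rng.random((b, n)) < pen
    return pat, mat, affected


def marker_counts(pat: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """Unordered marker genotype as M1 count."""
    return (pat < 2).astype(np.int8) + (mat < 2).astype(np.int8)


def ascertained_batch(
    ta: TemplateArrays,
    hap_freqs: np.ndarray,
    pen_matrix: np.ndarray,
    rng: np.random.Generator,
    count: int,
    attempt_cap: int = 10**6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Rejection-sample ``count`` pedigrees with >=1 affected nonfounder.

    Returns (marker_counts, affected, paternal, maternal) with ``count``
    rows each.  Aborts with a diagnostic once ``attempt_cap`` pedigrees have
    been generated without filling the request.
    """
    nonf = list(ta.nonfounder_idx)
    got_g, got_a, got_p, got_m = [], [], [], []
    total = 0
    attempts = 0
    while total < count:
        b = max(32, 2 * (count - total))
        if attempts + b > attempt_cap:
            b = attempt_cap - attempts
            if b <= 0:
                raise RuntimeError(
                    f"template {ta.template.name}: ascertainment acceptance "
                    f"too low; gave up after {attempts} attempts "
                    f"({total}/{count} accepted)"
                )
        attempts += b
        pat, mat, aff = drop_batch(ta, hap_freqs, pen_matrix, rng, b)
        keep = aff[:, nonf].any(axis=1)
        got_p.append(pat[keep])
        got_m.append(mat[keep])
        got_a.append(aff[keep])
        total += int(keep.sum())
    pat = np.concatenate(got_p)[:count]
    mat = np.concatenate(got_m)[:count]
    aff = np.concatenate(got_a)[:count]
    return marker_counts(pat, mat), aff, pat, mat


# ---------------------------------------------------------------------------
# vectorised phase resolution and components
# ---------------------------------------------------------------------------


def phase_scores_batch(
    g: np.ndarray, ta: TemplateArrays
) -> tuple[np.ndarray, np.ndarray]:
    """Paternal/maternal allele scores for complete genotype-count rows.

    Mirrors :func:`gdti.scoring.decompose_scores`: homozygotes score (0,0)
    or (1,1); heterozygotes default to (0.5, 0.5) and are resolved to (1,0)
    or (0,1) when one parental origin of M1 is forced by the parents'
    genotypes (the only ambiguous nonfounder case is both parents
    heterozygous).  Input must be Mendelian-consistent.
    """
    xp = np.where(g == 2, 1.0, np.where(g == 1, 0.5, 0.0))
    xm = xp.copy()
    for child, father, mother in ta.trios:
        het = g[:, child] == 1
        gf, gm = g[:, father], g[:, mother]
        pat_m1 = het & ((gf == 2) | (gm == 0))
        mat_m1 = het & ((gm == 2) | (gf == 0))
        xp[pat_m1, child] = 1.0
        xm[pat_m1, child] = 0.0
        xp[mat_m1, child] = 0.0
        xm[mat_m1, child] = 1.0
    return xp, xm


def batch_components(
    g: np.ndarray, aff: np.ndarray, ta: TemplateArrays
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """All six components per pedigree row plus the validity mask.

    Rows with no affected or no unaffected member are invalid (skipped by
    every statistic); their component values are zeroed.
    """
    xp, xm = phase_scores_batch(g, ta)
    a = aff.sum(axis=1)
    valid = (a > 0) & (a < ta.n)
    comp = components_closed_form(xp[valid], xm[valid], aff[valid])
    out = {}
    for key, values in comp.items():
        full = np.zeros(g.shape[0])
        full[valid] = values
        out[key] = full
    return out, valid


def typed_scores_s(
    g: np.ndarray, aff: np.ndarray, typed_idx: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """GDT-ME pedigree scores using typed members only.

    Returns (s, valid); untyped members are excluded from the pair sums and
    from the 1/N scaling, matching the object-level behaviour of dropping
    untyped individuals.
    """
    idx = list(typed_idx)
    x = g[:, idx].astype(float)
    a_sub = aff[:, idx]
    n_t = len(idx)
    n_aff = a_sub.sum(axis=1)
    valid = (n_aff > 0) & (n_aff < n_t)
    u = n_t - n_aff
    sum_aff = (x * a_sub).sum(axis=1)
    sum_un = (x * ~a_sub).sum(axis=1)
    s = (u * sum_aff - n_aff * sum_un) / n_t
    s[~valid] = 0.0
    return s, valid


def gdt_variances(
    g: np.ndarray,
    aff: np.ndarray,
    ta: TemplateArrays,
    typed_idx: tuple[int, ...],
    p: float,
) -> np.ndarray:
    """Kinship-based variances V_i = (1/N^2) a' C a over typed members."""
    idx = list(typed_idx)
    n_t = len(idx)
    a_sub = aff[:, idx]
    n_aff = a_sub.sum(axis=1)
    u = n_t - n_aff
    a_vec = np.where(a_sub, u[:, None], -n_aff[:, None]).astype(float)
    c = 4.0 * ta.phi[np.ix_(idx, idx)] * p * (1.0 - p)
    return np.einsum("bi,ij,bj->b", a_vec, c, a_vec) / n_t**2


# ---------------------------------------------------------------------------
# Monte-Carlo completion machinery (per template)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def completion_grid(m: int) -> np.ndarray:
    """All 3^m assignments of M1 counts to m missing members, shape (3^m, m)."""
    if m == 0:
        return np.zeros((1, 0), dtype=np.int8)
    return (
        np.indices((3,) * m).reshape(m, -1).T.astype(np.int8)
    )


def completion_weights(
    g_obs: np.ndarray, completions: np.ndarray, ta: TemplateArrays, p: float
) -> tuple[np.ndarray, np.ndarray]:
    """Joint weights P(G_o, completion) for one pedigree.

    ``g_obs`` is the full genotype-count row (values at missing positions are
    ignored).  Returns the completed genotype matrix (C, n) and the weight
    per completion.
    """
    c = completions.shape[0]
    g = np.tile(g_obs, (c, 1))
    g[:, list(ta.missing_idx)] = completions
    prior = founder_prior(p)
    w = prior[g[:, list(ta.founder_idx)]].prod(axis=1)
    if ta.trios:
        child = [t[0] for t in ta.trios]
        father = [t[1] for t in ta.trios]
        mother = [t[2] for t in ta.trios]
        w = w * _T3[g[:, father], g[:, mother], g[:, child]].prod(axis=1)
    return g, w


def mc_components_batch(
    g: np.ndarray,
    aff: np.ndarray,
    ta: TemplateArrays,
    p: float,
    k: int,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Monte-Carlo-averaged components for a batch of incomplete pedigrees.

    For each pedigree the missing genotypes are drawn K times from the exact
    conditional ``P(G_m | G_o)`` (multinomial over the enumerated
    completions) and each component is averaged over the draws.
    """
    b = g.shape[0]
    completions = completion_grid(len(ta.missing_idx))
    keys = ("s", "d1", "d2", "i11", "i22", "i12")
    out = {key: np.zeros(b) for key in keys}
    a = aff.sum(axis=1)
    valid = (a > 0) & (a < ta.n)
    for row in range(b):
        if not valid[row]:
            continue
        g_full, w = completion_weights(g[row], completions, ta, p)
        total = w.sum()
        if total <= 0.0:
            raise ValueError("Mendelian-impossible observed genotypes")
        counts = rng.multinomial(k, w / total)
        hit = counts > 0
        comp = components_closed_form(
            *phase_scores_batch(g_full[hit], ta),
            np.broadcast_to(aff[row], (int(hit.sum()), ta.n)),
        )
        weights = counts[hit] / k
        for key in keys:
            out[key][row] = float(comp[key] @ weights)
    return out, valid
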
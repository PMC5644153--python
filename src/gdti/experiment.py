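"""Size and power experiments over simulated pedigree studies.

A :class:`StudyDesign` fixes everything that defines one simulation cell:
pedigree-template counts (possibly split over subpopulations with their own
haplotype frequencies, for population-stratification scenarios), the
penetrance model, and whether the designated genotypes are masked
(incomplete data).  :func:`run_experiment` simulates replicates of the
design, applies the requested tests and reports per-test rejection
proportions at a chosen significance level.

Test semantics per replicate mirror the simulation study conventions:

* ``gdti`` is always evaluated on the complete (unmasked) genotypes;
* ``gdt_me`` and ``gdt`` drop untyped individuals when the design is
  incomplete;
* ``mcgdti`` and ``mcgdt_me`` impute the masked genotypes by Monte-Carlo
  sampling (K draws per pedigree) using either the design's true marker
  allele frequency or one estimated from the typed founders, and reduce
  exactly to GDTI / GDT-ME when nothing is masked.

Each replicate uses an independent substream of the master seed, so partial
runs and reruns are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import _engine
from .association import chi2_quadratic_form
from .montecarlo import MCConfig
from .simulate import (
    IMPRINTING_MODELS,
    LD_SETTINGS,
    SIZE_P_D,
    SIZE_SETTINGS,
    TEMPLATES,
    HaplotypeFrequencies,
    PedigreeTemplate,
    PenetranceModel,
    null_haplotype_freqs,
)

__all__ = [
    "DesignGroup",
    "StudyDesign",
    "ExperimentResult",
    "run_experiment",
    "table1_design",
    "power_design",
    "ps_design",
    "load_design",
    "AVAILABLE_TESTS",
]

AVAILABLE_TESTS = ("gdti", "gdt_me", "gdt", "mcgdti", "mcgdt_me")

#: Penetrances shared by both subpopulations in the stratification study.
PS_PENETRANCE = PenetranceModel(f2=0.45, f10=0.30, f01=0.30, f0=0.20)


@dataclass
class DesignGroup:
    """Pedigree counts per template drawn from one set of haplotype freqs."""

    counts: dict[str, int]
    haplotypes: HaplotypeFrequencies

    def __post_init__(self) -> None:
        for name, count in self.counts.items():
            if count < 0:
                raise ValueError(f"negative count for template {name}")


@dataclass
class StudyDesign:
    """One simulation cell: who is simulated, from what, and what is masked."""

    groups: list[DesignGroup]
    penetrance: PenetranceModel
    incomplete: bool = False
    attempt_cap: int = 10**6
    templates: dict[str, PedigreeTemplate] = field(
        default_factory=lambda: dict(TEMPLATES)
    )

    def template(self, name: str) -> PedigreeTemplate:
        try:
            return self.templates[name]
        except KeyError:
            raise KeyError(f"unknown pedigree template {name!r}") from None

    @property
    def n_pedigrees(self) -> int:
        return sum(c for g in self.groups for c in g.counts.values())


def table1_design(
    setting: int, per_template: int = 30, incomplete: bool = True
) -> StudyDesign:
    """Null (no association, no imprinting) design for one size setting (1-9).

    Settings sweep P_M1 over {0.15, 0.35, 0.25} and the homozygote
    penetrances over RR = 1.500, 1.833, 2.182 with f1 = (f2+f0)/2, at
    linkage equilibrium (haplotype frequencies are allele-frequency
    products) and P_D = 0.25.
    """
    if not 1 <= setting <= len(SIZE_SETTINGS):
        raise ValueError(f"setting must be 1..{len(SIZE_SETTINGS)}")
    p_m1, pen = SIZE_SETTINGS[setting - 1]
    counts = {name: per_template for name in TEMPLATES}
    return StudyDesign(
        groups=[DesignGroup(counts, null_haplotype_freqs(SIZE_P_D, p_m1))],
        penetrance=pen,
        incomplete=incomplete,
    )


def power_design(
    ld: str = "LD1",
    imprinting: str = "complete",
    rr_index: int = 0,
    per_template: int = 50,
    incomplete: bool = True,
) -> StudyDesign:
    """Power design: one LD setting x one imprinting model x one RR level."""
    pen = IMPRINTING_MODELS[imprinting][rr_index]
    counts = {name: per_template for name in TEMPLATES}
    return StudyDesign(
        groups=[DesignGroup(counts, LD_SETTINGS[ld])],
        penetrance=pen,
        incomplete=incomplete,
    )


def ps_design(scenario: int = 1, incomplete: bool = True) -> StudyDesign:
    """Population-stratification designs mixing two subpopulations.

    Marker and DSL are in linkage equilibrium with P_D = P_M1 = 0.1 in the
    first subpopulation and 0.5 in the second; penetrances are shared.
    Scenario 1 draws 50 pedigrees of every template from each subpopulation;
    scenario 2 draws 100 two-generation and 100 three-generation pedigrees
    from the first and 100 four-generation pedigrees from the second, so the
    subpopulations also differ in structure and missingness burden.
    """
    sub1 = null_haplotype_freqs(0.1, 0.1)
    sub2 = null_haplotype_freqs(0.5, 0.5)
    if scenario == 1:
        groups = [
            DesignGroup({name: 50 for name in TEMPLATES}, sub1),
            DesignGroup({name: 50 for name in TEMPLATES}, sub2),
        ]
    elif scenario == 2:
        groups = [
            DesignGroup({"two_gen_5": 100, "three_gen_10": 100}, sub1),
            DesignGroup({"four_gen_12": 100}, sub2),
        ]
    else:
        raise ValueError("scenario must be 1 or 2")
    return StudyDesign(
        groups=groups, penetrance=PS_PENETRANCE, incomplete=incomplete
    )


# ---------------------------------------------------------------------------
# experiment execution
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    """Per-test rejection proportions over the simulated replicates."""

    table: pd.DataFrame
    alpha: float
    replicates: int
    seed: int

    def rejection_rate(self, test: str) -> float:
        return float(self.table.loc[test, "rejection_rate"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="test")

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return (
            f"ExperimentResult(alpha={self.alpha}, replicates="
            f"{self.replicates})\n{self.table}"
        )


def _normal_p(total_s: float, total_v: float) -> tuple[float, float]:
    if total_v <= 0.0:
        return 0.0, 1.0
    z = total_s / np.sqrt(total_v)
    return z, float(2.0 * stats.norm.sf(abs(z)))


class _ReplicateData:
    """Simulated arrays for one replicate, shared across the tests."""

    def __init__(
        self,
        design: StudyDesign,
        rng: np.random.Generator,
        unknown_affection_rate: float,
    ):
        self.design = design
        self.batches: list[tuple[_engine.TemplateArrays, np.ndarray, np.ndarray]] = []
        for group in design.groups:
            for tname, count in group.counts.items():
                if count == 0:
                    continue
                ta = _engine.TemplateArrays.from_template(design.template(tname))
                g, aff, _, _ = _engine.ascertained_batch(
                    ta,
                    group.haplotypes.as_array(),
                    design.penetrance.as_matrix(),
                    rng,
                    count,
                    attempt_cap=design.attempt_cap,
                )
                if unknown_affection_rate > 0.0:
                    # members with an unknown status are analysed as
                    # unaffected (ascertainment uses the true statuses)
                    unknown = rng.random(aff.shape) < unknown_affection_rate
                    aff = aff & ~unknown
                self.batches.append((ta, g.astype(np.int8), aff))

    def typed_idx(self, ta: _engine.TemplateArrays) -> tuple[int, ...]:
        if self.design.incomplete:
            return ta.typed_idx
        return tuple(range(ta.n))

    def estimate_p(self, mode: str = "founders") -> float:
        m1 = 0
        total = 0
        for ta, g, _ in self.batches:
            typed = set(self.typed_idx(ta))
            if mode == "founders":
                idx = [i for i in ta.founder_idx if i in typed]
            else:
                idx = sorted(typed)
            if not idx:
                continue
            m1 += int(g[:, idx].sum())
            total += 2 * g.shape[0] * len(idx)
        if total == 0:
            raise ValueError("no typed individuals to estimate the frequency")
        return m1 / total


def _test_pvalue(
    name: str,
    data: _ReplicateData,
    mc: MCConfig,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """(statistic, p-value) of one test on one replicate."""
    design = data.design
    if name == "gdti":
        d_sum = np.zeros(2)
        info = np.zeros((2, 2))
        for ta, g, aff in data.batches:
            comp, valid = _engine.batch_components(g, aff, ta)
            d_sum += (comp["d1"][valid].sum(), comp["d2"][valid].sum())
            info += np.array(
                [
                    [comp["i11"][valid].sum(), comp["i12"][valid].sum()],
                    [comp["i12"][valid].sum(), comp["i22"][valid].sum()],
                ]
            )
        stat, _, p, _ = chi2_quadratic_form(d_sum, info)
        return stat, p

    if name in ("gdt_me", "gdt"):
        total_s = 0.0
        total_v = 0.0
        p_hat = data.estimate_p("founders") if name == "gdt" else None
        for ta, g, aff in data.batches:
            typed = data.typed_idx(ta)
            s, valid = _engine.typed_scores_s(g, aff, typed)
            total_s += float(s[valid].sum())
            if name == "gdt_me":
                total_v += float((s[valid] ** 2).sum())
            else:
                v = _engine.gdt_variances(g, aff, ta, typed, p_hat)
                total_v += float(v[valid].sum())
        return _normal_p(total_s, total_v)

    if name in ("mcgdti", "mcgdt_me"):
        if mc.freq_mode == "true":
            p_samp = float(mc.allele_freq)
        elif mc.freq_mode == "founders":
            p_samp = data.estimate_p("founders")
        else:
            p_samp = data.estimate_p("all")
        d_sum = np.zeros(2)
        info = np.zeros((2, 2))
        total_s = 0.0
        total_ss = 0.0
        for ta, g, aff in data.batches:
            if design.incomplete and ta.missing_idx:
                comp, valid = _engine.mc_components_batch(
                    g, aff, ta, p_samp, mc.k, rng
                )
            else:
                comp, valid = _engine.batch_components(g, aff, ta)
            if name == "mcgdti":
                d_sum += (comp["d1"][valid].sum(), comp["d2"][valid].sum())
                info += np.array(
                    [
                        [comp["i11"][valid].sum(), comp["i12"][valid].sum()],
                        [comp["i12"][valid].sum(), comp["i22"][valid].sum()],
                    ]
                )
            else:
                total_s += float(comp["s"][valid].sum())
                total_ss += float((comp["s"][valid] ** 2).sum())
        if name == "mcgdti":
            stat, _, p, _ = chi2_quadratic_form(d_sum, info)
            return stat, p
        return _normal_p(total_s, total_ss)

    raise ValueError(f"unknown test {name!r}; available: {AVAILABLE_TESTS}")


def run_experiment(
    design: StudyDesign,
    tests: list[str] | tuple[str, ...] = ("gdti",),
    replicates: int = 1000,
    alpha: float = 0.01,
    mc: MCConfig | None = None,
    seed: int = 0,
    unknown_affection_rate: float = 0.0,
) -> ExperimentResult:
    """Simulate ``replicates`` studies and report per-test rejection rates.

    Replicate ``r`` uses the substream ``SeedSequence(seed, spawn_key=(r,))``
    of the master seed, so results are reproducible and independent of which
    other replicates are run.  A test rejects when its p-value is at most
    ``alpha``.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    for t in tests:
        if t not in AVAILABLE_TESTS:
            raise ValueError(f"unknown test {t!r}; available: {AVAILABLE_TESTS}")
    if mc is None:
        mc = MCConfig(k=50, freq_mode="founders")
    rejections = {t: 0 for t in tests}
    stat_sums = {t: 0.0 for t in tests}
    for rep in range(replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(rep,))
        )
        data = _ReplicateData(design, rng, unknown_affection_rate)
        for t in tests:
            stat, p = _test_pvalue(t, data, mc, rng)
            stat_sums[t] += stat
            if p <= alpha:
                rejections[t] += 1
    table = pd.DataFrame(
        {
            "rejections": [rejections[t] for t in tests],
            "replicates": replicates,
            "rejection_rate": [rejections[t] / replicates for t in tests],
            "mean_statistic": [stat_sums[t] / replicates for t in tests],
        },
        index=list(tests),
    )
    return ExperimentResult(
        table=table, alpha=alpha, replicates=replicates, seed=seed
    )


# ---------------------------------------------------------------------------
# design files
# ---------------------------------------------------------------------------


def _haplotypes_from_config(node: dict) -> HaplotypeFrequencies:
    if "null" in node:
        return null_haplotype_freqs(node["null"]["p_d"], node["null"]["p_m1"])
    return HaplotypeFrequencies(
        DM1=node["DM1"], dM1=node["dM1"], DM2=node["DM2"], dM2=node["dM2"]
    )


def load_design(source) -> StudyDesign:
    """Build a StudyDesign from a YAML file (path) or a parsed mapping.

    Keys: ``templates`` (name -> count), ``haplotypes`` (four frequencies or
    ``null: {p_d, p_m1}``), ``penetrances`` (f2/f10/f01/f0), ``incomplete``;
    an optional ``ps`` list of ``{templates, haplotypes}`` groups replaces
    the single-group form.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    known = {"templates", "haplotypes", "penetrances", "incomplete", "ps",
             "attempt_cap"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown design keys: {sorted(unknown)}")
    pen_node = cfg["penetrances"]
    pen = PenetranceModel(
        f2=pen_node["f2"],
        f10=pen_node["f10"],
        f01=pen_node["f01"],
        f0=pen_node["f0"],
    )
    if "ps" in cfg:
        groups = [
            DesignGroup(
                {str(k): int(v) for k, v in sub["templates"].items()},
                _haplotypes_from_config(sub["haplotypes"]),
            )
            for sub in cfg["ps"]
        ]
    else:
        groups = [
            DesignGroup(
                {str(k): int(v) for k, v in cfg["templates"].items()},
                _haplotypes_from_config(cfg["haplotypes"]),
            )
        ]
    for group in groups:
        for name in group.counts:
            if name not in TEMPLATES:
                raise ValueError(f"unknown pedigree template {name!r}")
    return StudyDesign(
        groups=groups,
        penetrance=pen,
        incomplete=bool(cfg.get("incomplete", False)),
        attempt_cap=int(cfg.get("attempt_cap", 10**6)),
    )
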
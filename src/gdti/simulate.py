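"""Gene-dropping simulator for two-locus pedigree data.

A diallelic disease susceptibility locus (DSL, alleles D/d) and a diallelic
marker (M1/M2) are in complete linkage: each founder draws two of the four
haplotypes DM1, dM1, DM2, dM2 i.i.d. from the population haplotype
frequencies, and every nonfounder inherits one haplotype from each parent,
chosen uniformly from the parent's two (no recombination).  Affection status
is Bernoulli with a penetrance that depends on the *ordered* DSL genotype
(paternal allele written first), so parent-of-origin (imprinting) effects are
expressed as ``f10 != f01``.

Three built-in pedigree structures are provided: a two-generation family of
5, a three-generation pedigree of 10 and a four-generation pedigree of 12.
Each carries the identifiers whose genotypes are masked in incomplete-data
analyses (a founder in the two-generation family; a founder and two
married-in spouses in the three-generation pedigree; a founder and a
married-in spouse in the four-generation pedigree).  The exact topologies are
configurable; the statistics under study are driven by the discordant-pair
counts and the missingness burden rather than fine topology details.

Sampled pedigrees enter a study only if they contain at least one affected
nonfounder (the ascertainment rule); the analysis layer additionally requires
at least one affected and one unaffected member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import Individual, MarkerGenotype, Pedigree, PedigreeSet

__all__ = [
    "HaplotypeFrequencies",
    "PenetranceModel",
    "PedigreeTemplate",
    "SimulatedPedigree",
    "TEMPLATES",
    "ld_coefficient",
    "null_haplotype_freqs",
    "simulate_pedigree",
    "ascertain",
    "apply_missingness",
    "simulate_replicate",
    "LD_SETTINGS",
    "HOMOZYGOTE_PENETRANCES",
    "IMPRINTING_MODELS",
    "SIZE_SETTINGS",
]

# haplotype codes used throughout the simulator
DM1, dM1, DM2, dM2 = 0, 1, 2, 3


@dataclass(frozen=True)
class HaplotypeFrequencies:
    """Population frequencies of the four marker-DSL haplotypes.

    Attribute names follow the haplotype labels: ``DM1`` is the frequency of
    the haplotype carrying disease allele D and marker allele M1, etc.
    """

    DM1: float
    dM1: float
    DM2: float
    dM2: float

    def __post_init__(self) -> None:
        freqs = self.as_array()
        if np.any(freqs < 0) or np.any(freqs > 1):
            raise ValueError(f"haplotype frequencies must be in [0,1]: {self}")
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"haplotype frequencies must sum to 1, got {freqs.sum()!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.DM1, self.dM1, self.DM2, self.dM2])

    @property
    def p_d(self) -> float:
        """Disease allele frequency P_D."""
        return self.DM1 + self.DM2

    @property
    def p_m1(self) -> float:
        """Marker allele frequency P_M1."""
        return self.DM1 + self.dM1

    @property
    def ld(self) -> float:
        """Linkage disequilibrium coefficient P(DM1) - P_D * P_M1."""
        return self.DM1 - self.p_d * self.p_m1

    @classmethod
    def null(cls, p_d: float, p_m1: float) -> "HaplotypeFrequencies":
        """Product (linkage-equilibrium) frequencies: LD = 0."""
        if not (0.0 < p_d < 1.0 and 0.0 < p_m1 < 1.0):
            raise ValueError("allele frequencies must be in (0,1)")
        return cls(
            DM1=p_d * p_m1,
            dM1=(1 - p_d) * p_m1,
            DM2=p_d * (1 - p_m1),
            dM2=(1 - p_d) * (1 - p_m1),
        )


def ld_coefficient(h: HaplotypeFrequencies) -> float:
    """LD = P(DM1) - P_D * P_M1."""
    return h.ld


def null_haplotype_freqs(p_d: float, p_m1: float) -> HaplotypeFrequencies:
    """Haplotype frequencies under no association (product of allele freqs)."""
    return HaplotypeFrequencies.null(p_d, p_m1)


@dataclass(frozen=True)
class PenetranceModel:
    """Penetrances of the ordered DSL genotypes D/D, D/d, d/D, d/d.

    The paternal allele is written first: ``f10`` applies when D came from
    the father, ``f01`` when it came from the mother.  ``f10 == f01`` means
    no imprinting.
    """

    f2: float
    f10: float
    f01: float
    f0: float

    def __post_init__(self) -> None:
        for name in ("f2", "f10", "f01", "f0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"penetrance {name}={v} outside [0,1]")

    @property
    def relative_risk(self) -> float:
        """Homozygote relative risk RR = f2 / f0."""
        return self.f2 / self.f0

    @property
    def has_imprinting(self) -> bool:
        return self.f10 != self.f01

    def as_matrix(self) -> np.ndarray:
        """Penetrance indexed by (paternal D carried, maternal D carried)."""
        return np.array([[self.f0, self.f01], [self.f10, self.f2]])

    @classmethod
    def no_imprinting(cls, f2: float, f0: float) -> "PenetranceModel":
        f1 = (f2 + f0) / 2.0
        return cls(f2=f2, f10=f1, f01=f1, f0=f0)

    @classmethod
    def complete_imprinting(cls, f2: float, f0: float) -> "PenetranceModel":
        """Fully silenced maternal copy: f10 = f2, f01 = f0."""
        return cls(f2=f2, f10=f2, f01=f0, f0=f0)


# -- study constants --------------------------------------------------------

#: Haplotype-frequency scenarios for the power study (P_D = 0.25 throughout).
LD_SETTINGS: dict[str, HaplotypeFrequencies] = {
    "LD1": HaplotypeFrequencies(0.13, 0.02, 0.12, 0.73),
    "LD2": HaplotypeFrequencies(0.23, 0.12, 0.02, 0.63),
    "LD3": HaplotypeFrequencies(0.22, 0.03, 0.03, 0.72),
}

#: Homozygote penetrance pairs (f2, f0); RR = 1.500, 1.833, 2.182.
HOMOZYGOTE_PENETRANCES: tuple[tuple[float, float], ...] = (
    (0.390, 0.260),
    (0.440, 0.240),
    (0.480, 0.220),
)

#: Imprinting-effect models per homozygote pair, keyed by degree of imprinting.
IMPRINTING_MODELS: dict[str, tuple[PenetranceModel, ...]] = {
    "no": tuple(
        PenetranceModel.no_imprinting(f2, f0)
        for f2, f0 in HOMOZYGOTE_PENETRANCES
    ),
    "incomplete": (
        PenetranceModel(0.390, 0.370, 0.280, 0.260),
        PenetranceModel(0.440, 0.420, 0.260, 0.240),
        PenetranceModel(0.480, 0.460, 0.240, 0.220),
    ),
    "complete": tuple(
        PenetranceModel.complete_imprinting(f2, f0)
        for f2, f0 in HOMOZYGOTE_PENETRANCES
    ),
}

#: Null (size) settings: (P_M1, no-imprinting penetrance model), P_D = 0.25.
SIZE_SETTINGS: tuple[tuple[float, PenetranceModel], ...] = tuple(
    (p_m1, PenetranceModel.no_imprinting(f2, f0))
    for p_m1 in (0.15, 0.35, 0.25)
    for f2, f0 in HOMOZYGOTE_PENETRANCES
)

SIZE_P_D = 0.25


# -- pedigree templates -----------------------------------------------------


@dataclass(frozen=True)
class PedigreeTemplate:
    """A fixed pedigree structure for the simulator.

    Members are listed parents-before-offspring; founders have ``None``
    parent entries.  ``missing_iids`` are the members whose genotypes are
    masked for incomplete-data analyses.
    """

    name: str
    iids: tuple[str, ...]
    fathers: tuple[str | None, ...]
    mothers: tuple[str | None, ...]
    sexes: tuple[int, ...]
    missing_iids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.iids)
        if not (len(self.fathers) == len(self.mothers) == len(self.sexes) == n):
            raise ValueError(f"template {self.name}: ragged member arrays")
        seen: set[str] = set()
        for iid, f, m in zip(self.iids, self.fathers, self.mothers):
            if (f is None) != (m is None):
                raise ValueError(f"template {self.name}: half-specified parents")
            if f is not None and (f not in seen or m not in seen):
                raise ValueError(
                    f"template {self.name}: parents of {iid} must be listed "
                    "before their offspring"
                )
            seen.add(iid)
        if not set(self.missing_iids) <= seen:
            raise ValueError(f"template {self.name}: unknown missing id")

    @property
    def n(self) -> int:
        return len(self.iids)

    def founder_flags(self) -> np.ndarray:
        return np.array([f is None for f in self.fathers])

    def skeleton(self, fid: str = "0") -> Pedigree:
        """Pedigree of this structure with no genotypes or phenotypes."""
        return Pedigree(
            fid,
            [
                Individual(iid=i, father_iid=f, mother_iid=m, sex=s)
                for i, f, m, s in zip(
                    self.iids, self.fathers, self.mothers, self.sexes
                )
            ],
        )


def _couple_with_children(
    name: str, missing: tuple[str, ...]
) -> PedigreeTemplate:
    return PedigreeTemplate(
        name=name,
        iids=("1", "2", "3", "4", "5"),
        fathers=(None, None, "1", "1", "1"),
        mothers=(None, None, "2", "2", "2"),
        sexes=(1, 2, 1, 2, 1),
        missing_iids=missing,
    )


TWO_GEN_5 = _couple_with_children("two_gen_5", missing=("1",))

THREE_GEN_10 = PedigreeTemplate(
    name="three_gen_10",
    #      1     2     3      4     5      6     7    8    9    10
    iids=("1", "2", "3", "4", "5", "6", "7", "8", "9", "10"),
    fathers=(None, None, "1", None, None, "1", "3", "3", "5", "5"),
    mothers=(None, None, "2", None, None, "2", "4", "4", "6", "6"),
    sexes=(1, 2, 1, 2, 1, 2, 1, 2, 1, 2),
    missing_iids=("1", "4", "5"),
)

FOUR_GEN_12 = PedigreeTemplate(
    name="four_gen_12",
    iids=("1", "2", "3", "4", "5", "6", "7", "8", "9", "10", "11", "12"),
    fathers=(None, None, None, "1", "1", "4", "4", "4", None, "6", "6", "6"),
    mothers=(None, None, None, "2", "2", "3", "3", "3", None, "9", "9", "9"),
    sexes=(1, 2, 2, 1, 2, 1, 2, 1, 2, 1, 2, 1),
    missing_iids=("1", "3"),
)

TEMPLATES: dict[str, PedigreeTemplate] = {
    t.name: t for t in (TWO_GEN_5, THREE_GEN_10, FOUR_GEN_12)
}


# -- gene dropping ----------------------------------------------------------


@dataclass
class SimulatedPedigree:
    """A gene-dropped pedigree plus its latent two-locus haplotypes.

    ``paternal``/``maternal`` hold haplotype codes (0=DM1, 1=dM1, 2=DM2,
    3=dM2) per member in template order; the :class:`Pedigree` exposes only
    the unordered marker genotypes and the affection statuses.
    """

    pedigree: Pedigree
    template: PedigreeTemplate
    paternal: np.ndarray
    maternal: np.ndarray

    @property
    def ordered_dsl(self) -> list[str]:
        """Ordered DSL genotypes, paternal allele first (e.g. 'D/d')."""
        pat = np.where(self.paternal % 2 == 0, "D", "d")
        mat = np.where(self.maternal % 2 == 0, "D", "d")
        return [f"{a}/{b}" for a, b in zip(pat, mat)]


def _marker_counts(pat: np.ndarray, mat: np.ndarray) -> np.ndarray:
    return (pat < 2).astype(np.int8) + (mat < 2).astype(np.int8)


def _pedigree_from_arrays(
    template: PedigreeTemplate,
    fid: str,
    counts: np.ndarray,
    aff: np.ndarray,
) -> Pedigree:
    members = [
        Individual(
            iid=i,
            father_iid=f,
            mother_iid=m,
            sex=s,
            affection=int(a),
            genotype=MarkerGenotype.from_m1_count(int(c)),
        )
        for i, f, m, s, a, c in zip(
            template.iids,
            template.fathers,
            template.mothers,
            template.sexes,
            aff,
            counts,
        )
    ]
    return Pedigree(fid, members)


def simulate_pedigree(
    template: PedigreeTemplate,
    h: HaplotypeFrequencies,
    pen: PenetranceModel,
    rng: np.random.Generator,
    fid: str = "1",
) -> SimulatedPedigree:
    """Gene-drop one pedigree (no ascertainment applied)."""
    from . import _engine

    ta = _engine.TemplateArrays.from_template(template)
    pat, mat, aff = _engine.drop_batch(ta, h.as_array(), pen.as_matrix(), rng, 1)
    ped = _pedigree_from_arrays(
        template, fid, _marker_counts(pat[0], mat[0]), aff[0]
    )
    return SimulatedPedigree(
        pedigree=ped, template=template, paternal=pat[0], maternal=mat[0]
    )


def ascertain(ped: Pedigree) -> bool:
    """Study inclusion rule: at least one affected nonfounder."""
    return any(m.affection == 1 for m in ped.nonfounders)


def apply_missingness(ped: Pedigree, template: PedigreeTemplate) -> Pedigree:
    """Mask the genotypes of the template's designated members."""
    for iid in template.missing_iids:
        if iid not in ped:
            raise ValueError(
                f"pedigree {ped.fid}: missing id {iid!r} not a member"
            )
    return ped.with_genotypes({iid: None for iid in template.missing_iids})


def simulate_replicate(design, rng: np.random.Generator) -> PedigreeSet:
    """One replicate of a study design as a PedigreeSet.

    Pedigrees are rejection-sampled per template until the requested counts
    are met (at least one affected nonfounder each); with
    ``design.incomplete`` the designated genotypes are masked.  Family ids
    are sequential across groups and templates.
    """
    from . import _engine

    peds: list[Pedigree] = []
    fid = 0
    for group in design.groups:
        for tname, count in group.counts.items():
            if count == 0:
                continue
            template = design.template(tname)
            ta = _engine.TemplateArrays.from_template(template)
            counts, aff, _, _ = _engine.ascertained_batch(
                ta,
                group.haplotypes.as_array(),
                design.penetrance.as_matrix(),
                rng,
                count,
                attempt_cap=design.attempt_cap,
            )
            for row in range(count):
                fid += 1
                ped = _pedigree_from_arrays(
                    template, str(fid), counts[row], aff[row]
                )
                if design.incomplete:
                    ped = apply_missingness(ped, template)
                peds.append(ped)
    return PedigreeSet(peds)
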
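"""Decomposition of genotype scores into paternal and maternal allele scores.

The genotype score X of an individual counts its M1 alleles (0, 1 or 2).  To
detect parent-of-origin effects, X is split as X = X^(p) + X^(m), where the
paternal score X^(p) is 1 if an M1 allele was demonstrably transmitted by the
father, 0 if the father demonstrably transmitted M2, and 0.5 when the parental
origin of a heterozygote's M1 cannot be resolved (heterozygous founders, and
heterozygous nonfounders whose parents are both heterozygous).  The maternal
score X^(m) is defined symmetrically.

Phase is resolved from the parents' marker genotypes only; no information from
siblings, grandparents or offspring is used, so the scores of distinct
individuals are functions of their own trio of genotypes alone.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .pedigree import MarkerGenotype, Pedigree

__all__ = [
    "AlleleScores",
    "Phase",
    "genotype_score",
    "resolve_phase",
    "decompose_scores",
    "MendelianError",
    "IncompleteDataError",
]


class MendelianError(ValueError):
    """A genotype configuration impossible under Mendelian transmission."""


class IncompleteDataError(ValueError):
    """Complete-genotype operation applied to a pedigree with missing data."""


class Phase(enum.Enum):
    """Parental origin of the M1 allele of a heterozygote."""

    M1_PATERNAL = "M1_paternal"
    M1_MATERNAL = "M1_maternal"
    AMBIGUOUS = "ambiguous"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class AlleleScores:
    """Paternal/maternal allele score pair; xp + xm equals the genotype score."""

    xp: float
    xm: float

    def __post_init__(self) -> None:
        if self.xp not in (0.0, 0.5, 1.0) or self.xm not in (0.0, 0.5, 1.0):
            raise ValueError(f"allele scores must be 0, 0.5 or 1: {self}")

    @property
    def x(self) -> float:
        """Genotype score X = X^(p) + X^(m)."""
        return self.xp + self.xm


def genotype_score(g: MarkerGenotype) -> int:
    """Genotype score X: 0, 1, 2 for M2M2, M1M2, M1M1.

    Raises :class:`IncompleteDataError` if the genotype is missing.
    """
    if g is None:
        raise IncompleteDataError(
            "genotype score undefined for a missing genotype; complete "
            "genotypes (e.g. by Monte-Carlo sampling) first"
        )
    return g.m1_count


def resolve_phase(
    child: MarkerGenotype,
    father: MarkerGenotype | None,
    mother: MarkerGenotype | None,
    is_founder: bool = False,
) -> Phase:
    """Determine the parental origin of a child's M1 allele.

    Homozygotes need no phase (``NOT_APPLICABLE``).  Heterozygous founders are
    ``AMBIGUOUS``.  For a heterozygous nonfounder, each parental assignment of
    M1 is kept if it is Mendelian-consistent with both parents' genotypes; a
    unique survivor resolves the phase, two survivors (both parents
    heterozygous) are ``AMBIGUOUS``, none is a :class:`MendelianError`.
    """
    if child is None:
        raise IncompleteDataError("cannot resolve phase of a missing genotype")
    if not child.is_het:
        return Phase.NOT_APPLICABLE
    if is_founder:
        return Phase.AMBIGUOUS
    if father is None or mother is None:
        raise IncompleteDataError(
            "heterozygous nonfounder with an untyped parent: phase requires "
            "complete parental genotypes"
        )
    pat = {father.a, father.b}
    mat = {mother.a, mother.b}
    paternal_ok = 1 in pat and 2 in mat  # M1 from father, M2 from mother
    maternal_ok = 2 in pat and 1 in mat  # M2 from father, M1 from mother
    if paternal_ok and maternal_ok:
        return Phase.AMBIGUOUS
    if paternal_ok:
        return Phase.M1_PATERNAL
    if maternal_ok:
        return Phase.M1_MATERNAL
    raise MendelianError(
        f"heterozygous child impossible given parents {father} x {mother}"
    )


_HET_SCORES = {
    Phase.M1_PATERNAL: AlleleScores(1.0, 0.0),
    Phase.M1_MATERNAL: AlleleScores(0.0, 1.0),
    Phase.AMBIGUOUS: AlleleScores(0.5, 0.5),
}


def decompose_scores(ped: Pedigree) -> dict[str, AlleleScores]:
    """Allele scores (X^(p), X^(m)) for every member of a fully typed pedigree.

    Requires every member genotyped and Mendelian-consistent; errors name the
    offending individual.
    """
    out: dict[str, AlleleScores] = {}
    for ind in ped:
        g = ind.genotype
        if g is None:
            raise IncompleteDataError(
                f"pedigree {ped.fid}: individual {ind.iid} is untyped; use the "
                "Monte-Carlo tests for incomplete pedigrees"
            )
        if not g.is_het:
            s = 1.0 if g.m1_count == 2 else 0.0
            out[ind.iid] = AlleleScores(s, s)
            continue
        father = None if ind.is_founder else ped[ind.father_iid].genotype
        mother = None if ind.is_founder else ped[ind.mother_iid].genotype
        try:
            phase = resolve_phase(g, father, mother, is_founder=ind.is_founder)
        except MendelianError as exc:
            raise MendelianError(
                f"pedigree {ped.fid}, individual {ind.iid}: {exc}"
            ) from None
        out[ind.iid] = _HET_SCORES[phase]
    return out
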
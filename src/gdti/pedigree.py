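"""Pedigree data structures and LINKAGE/PLINK PED file input/output.

A :class:`Pedigree` is a collection of :class:`Individual` records linked by
parent identifiers.  Genotypes are for a single diallelic marker with alleles
coded 1 (``M1``) and 2 (``M2``); a genotype is either fully observed or fully
missing.  Affection status is stored as 1 (affected), 0 (unaffected) or
``None`` (unknown); unknown statuses are resolved by the analysis layer,
treating them as unaffected by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "MarkerGenotype",
    "Individual",
    "Pedigree",
    "PedigreeSet",
    "PedError",
    "MendelianViolation",
    "read_ped",
    "write_ped",
    "count_markers",
    "validate_mendelian",
]

MALE, FEMALE, UNKNOWN_SEX = 1, 2, 0
AFFECTED, UNAFFECTED = 1, 0


class PedError(ValueError):
    """Raised for malformed PED input or structurally invalid pedigrees."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class MarkerGenotype:
    """Unordered diallelic marker genotype with allele codes 1 and 2."""

    a: int
    b: int

    def __post_init__(self) -> None:
        if self.a not in (1, 2) or self.b not in (1, 2):
            raise PedError(f"allele codes must be 1 or 2, got ({self.a},{self.b})")

    @property
    def m1_count(self) -> int:
        """Number of M1 alleles carried (the genotype score X)."""
        return (self.a == 1) + (self.b == 1)

    @property
    def is_het(self) -> bool:
        return self.a != self.b

    def swapped(self) -> "MarkerGenotype":
        """Genotype after relabelling M1 <-> M2."""
        return MarkerGenotype(3 - self.a, 3 - self.b)

    @staticmethod
    def from_m1_count(x: int) -> "MarkerGenotype":
        if x not in (0, 1, 2):
            raise ValueError(f"M1 count must be 0, 1 or 2, got {x}")
        return (MarkerGenotype(2, 2), MarkerGenotype(1, 2), MarkerGenotype(1, 1))[x]

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        names = {1: "M1", 2: "M2"}
        a, b = sorted((self.a, self.b))
        return f"{names[a]}{names[b]}"


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_iid``/``mother_iid`` are either both ``None`` (a founder) or both
    set to identifiers present in the same pedigree.
    """

    iid: str
    father_iid: str | None = None
    mother_iid: str | None = None
    sex: int = UNKNOWN_SEX
    affection: int | None = None
    genotype: MarkerGenotype | None = None

    def __post_init__(self) -> None:
        if (self.father_iid is None) != (self.mother_iid is None):
            raise PedError(
                f"individual {self.iid}: father and mother must be both present "
                "or both absent"
            )
        if self.sex not in (MALE, FEMALE, UNKNOWN_SEX):
            raise PedError(f"individual {self.iid}: invalid sex code {self.sex}")
        if self.affection not in (AFFECTED, UNAFFECTED, None):
            raise PedError(f"individual {self.iid}: invalid affection {self.affection}")

    @property
    def is_founder(self) -> bool:
        return self.father_iid is None


class Pedigree:
    """A single pedigree: ordered members with parent links.

    Validates member uniqueness, parent existence, parental sex consistency
    and acyclicity of the parent graph on construction.
    """

    def __init__(self, fid: str, members: Iterable[Individual]):
        self.fid = str(fid)
        self.members: list[Individual] = list(members)
        self._index: dict[str, int] = {}
        for pos, ind in enumerate(self.members):
            if ind.iid in self._index:
                raise PedError(f"pedigree {fid}: duplicate individual id {ind.iid}")
            self._index[ind.iid] = pos
        for ind in self.members:
            if ind.is_founder:
                continue
            for role, pid, bad_sex in (
                ("father", ind.father_iid, FEMALE),
                ("mother", ind.mother_iid, MALE),
            ):
                if pid not in self._index:
                    raise PedError(
                        f"pedigree {fid}: {role} {pid} of {ind.iid} not in pedigree"
                    )
                if self[pid].sex == bad_sex:
                    raise PedError(
                        f"pedigree {fid}: {role} {pid} of {ind.iid} has "
                        "inconsistent sex"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 1 = on stack, 2 = done

        def visit(iid: str) -> None:
            if state.get(iid) == 2:
                return
            if state.get(iid) == 1:
                raise PedError(f"pedigree {self.fid}: parent graph contains a cycle")
            state[iid] = 1
            ind = self[iid]
            if not ind.is_founder:
                visit(ind.father_iid)
                visit(ind.mother_iid)
            state[iid] = 2

        for ind in self.members:
            visit(ind.iid)

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.members)

    def __getitem__(self, iid: str) -> Individual:
        return self.members[self._index[iid]]

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Pedigree)
            and self.fid == other.fid
            and self.members == other.members
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Pedigree({self.fid!r}, n={len(self)})"

    # -- derived structure --------------------------------------------------

    @property
    def n(self) -> int:
        """Pedigree size N_i."""
        return len(self.members)

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]

    def topological_order(self) -> list[Individual]:
        """Members ordered parents-before-offspring."""
        out: list[Individual] = []
        seen: set[str] = set()

        def visit(iid: str) -> None:
            if iid in seen:
                return
            ind = self[iid]
            if not ind.is_founder:
                visit(ind.father_iid)
                visit(ind.mother_iid)
            seen.add(iid)
            out.append(ind)

        for ind in self.members:
            visit(ind.iid)
        return out

    def resolved_affection(
        self, unknown_affection: str = "unaffected"
    ) -> dict[str, int]:
        """Map iid -> 0/1 after resolving unknown statuses.

        ``unknown_affection='unaffected'`` recodes unknowns as unaffected
        (the default); ``'exclude'`` drops them from the mapping, removing
        them from all discordant-pair sums.
        """
        if unknown_affection not in ("unaffected", "exclude"):
            raise ValueError(f"unknown_affection={unknown_affection!r}")
        out: dict[str, int] = {}
        for m in self.members:
            if m.affection is None:
                if unknown_affection == "exclude":
                    continue
                out[m.iid] = UNAFFECTED
            else:
                out[m.iid] = m.affection
        return out

    def n_affected(self, unknown_affection: str = "unaffected") -> int:
        """A_i: number of affected members after unknown-status resolution."""
        return sum(self.resolved_affection(unknown_affection).values())

    def n_unaffected(self, unknown_affection: str = "unaffected") -> int:
        """U_i = N_i - A_i (over members with resolved status)."""
        aff = self.resolved_affection(unknown_affection)
        return len(aff) - sum(aff.values())

    def with_genotypes(
        self, genotypes: Mapping[str, MarkerGenotype | None]
    ) -> "Pedigree":
        """Copy of the pedigree with genotypes replaced where given."""
        new = [
            replace(m, genotype=genotypes.get(m.iid, m.genotype))
            for m in self.members
        ]
        return Pedigree(self.fid, new)

    def genotyped_ids(self) -> list[str]:
        return [m.iid for m in self.members if m.genotype is not None]

    def missing_ids(self) -> list[str]:
        return [m.iid for m in self.members if m.genotype is None]


@dataclass
class PedigreeSet:
    """A collection of independent pedigrees for one marker."""

    pedigrees: list[Pedigree] = field(default_factory=list)
    marker_label: str = "marker"

    def __post_init__(self) -> None:
        fids = [p.fid for p in self.pedigrees]
        if len(set(fids)) != len(fids):
            dup = sorted({f for f in fids if fids.count(f) > 1})
            raise PedError(f"duplicate family ids: {', '.join(dup)}")

    def __len__(self) -> int:
        return len(self.pedigrees)

    def __iter__(self) -> Iterator[Pedigree]:
        return iter(self.pedigrees)


# ---------------------------------------------------------------------------
# PED file I/O (pre-MAKEPED LINKAGE / PLINK dialect)
# ---------------------------------------------------------------------------


def _parse_affection(token: str, coding: str, line: int) -> int | None:
    if coding == "1/2":
        table = {"1": UNAFFECTED, "2": AFFECTED, "0": None, "-9": None}
    elif coding == "0/1":
        table = {"0": UNAFFECTED, "1": AFFECTED, "-9": None}
    else:
        raise ValueError(f"affection_coding must be '1/2' or '0/1', got {coding!r}")
    try:
        return table[token]
    except KeyError:
        raise PedError(f"invalid affection code {token!r}", line) from None


def count_markers(path: str | Path) -> int:
    """Number of marker allele-pair column blocks in a PED file."""
    with open(path) as fh:
        for raw in fh:
            fields = raw.split()
            if not fields:
                continue
            extra = len(fields) - 6
            if extra < 2 or extra % 2:
                raise PedError("row does not contain complete allele pairs", 1)
            return extra // 2
    return 0


def read_ped(
    path: str | Path,
    affection_coding: str = "1/2",
    marker: int = 0,
    marker_label: str | None = None,
) -> PedigreeSet:
    """Parse a whitespace-delimited pre-MAKEPED PED file.

    Columns: FID IID PAT MAT SEX PHENO A1 A2 [A1 A2 ...]; 0 codes a missing
    parent, sex, phenotype or allele.  ``marker`` selects which allele-pair
    block to read (0-based) in multi-marker files.

    Raises
    ------
    PedError
        On malformed rows, allele codes outside {0,1,2}, half-missing
        genotypes, duplicate (fid, iid) pairs, or parents referenced but
        absent from their pedigree.
    """
    rows: dict[str, list[Individual]] = {}
    order: list[str] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            fields = raw.split()
            if not fields:
                continue
            if len(fields) < 8:
                raise PedError(
                    f"expected at least 8 columns, got {len(fields)}", lineno
                )
            if (len(fields) - 6) % 2:
                raise PedError("odd number of allele columns", lineno)
            fid, iid, pat, mat, sex_tok, pheno = fields[:6]
            col = 6 + 2 * marker
            if col + 1 >= len(fields):
                raise PedError(f"marker index {marker} out of range", lineno)
            if (fid, iid) in seen:
                raise PedError(f"duplicate individual ({fid}, {iid})", lineno)
            seen.add((fid, iid))
            try:
                sex = int(sex_tok)
            except ValueError:
                raise PedError(f"invalid sex code {sex_tok!r}", lineno) from None
            if sex not in (MALE, FEMALE, UNKNOWN_SEX):
                raise PedError(f"invalid sex code {sex_tok!r}", lineno)
            try:
                a, b = int(fields[col]), int(fields[col + 1])
            except ValueError:
                raise PedError("invalid allele code", lineno) from None
            if a not in (0, 1, 2) or b not in (0, 1, 2):
                raise PedError(f"allele codes must be 0, 1 or 2, got {a} {b}", lineno)
            if (a == 0) != (b == 0):
                raise PedError(f"half-missing genotype {a} {b}", lineno)
            genotype = None if a == 0 else MarkerGenotype(a, b)
            try:
                ind = Individual(
                    iid=iid,
                    father_iid=None if pat == "0" else pat,
                    mother_iid=None if mat == "0" else mat,
                    sex=sex,
                    affection=_parse_affection(pheno, affection_coding, lineno),
                    genotype=genotype,
                )
            except PedError as exc:
                raise PedError(str(exc), lineno) from None
            if fid not in rows:
                rows[fid] = []
                order.append(fid)
            rows[fid].append(ind)

    pedigrees = [Pedigree(fid, rows[fid]) for fid in order]
    if marker_label is None:
        marker_label = f"marker{marker + 1}"
    return PedigreeSet(pedigrees, marker_label=marker_label)


def write_ped(
    peds: PedigreeSet, path: str | Path, affection_coding: str = "1/2"
) -> None:
    """Write a PedigreeSet to a PED file (inverse of :func:`read_ped`).

    Member order is preserved; missing genotypes are emitted as ``0 0``.
    """
    if affection_coding == "1/2":
        aff_tok = {AFFECTED: "2", UNAFFECTED: "1", None: "0"}
    elif affection_coding == "0/1":
        aff_tok = {AFFECTED: "1", UNAFFECTED: "0", None: "-9"}
    else:
        raise ValueError(f"affection_coding must be '1/2' or '0/1'")
    with open(path, "w") as fh:
        for ped in peds:
            for m in ped:
                g = ("0", "0") if m.genotype is None else (
                    str(m.genotype.a),
                    str(m.genotype.b),
                )
                fh.write(
                    " ".join(
                        (
                            ped.fid,
                            m.iid,
                            m.father_iid or "0",
                            m.mother_iid or "0",
                            str(m.sex),
                            aff_tok[m.affection],
                            *g,
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Mendelian validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MendelianViolation:
    fid: str
    iid: str
    message: str


def _parent_alleles(g: MarkerGenotype | None) -> set[int]:
    """Alleles a parent can transmit (both codes if untyped)."""
    return {1, 2} if g is None else {g.a, g.b}


def _compatible(child: MarkerGenotype, pat: set[int], mat: set[int]) -> bool:
    return any(
        sorted((p, m)) == sorted((child.a, child.b)) for p in pat for m in mat
    )


def validate_mendelian(ped: Pedigree) -> list[MendelianViolation]:
    """List every genotyped nonfounder incompatible with its typed parents.

    Members with missing genotypes are never reported; an empty list means
    the pedigree is Mendelian-consistent.
    """
    out = []
    for ind in ped.nonfounders:
        if ind.genotype is None:
            continue
        pat = _parent_alleles(ped[ind.father_iid].genotype)
        mat = _parent_alleles(ped[ind.mother_iid].genotype)
        if not _compatible(ind.genotype, pat, mat):
            out.append(
                MendelianViolation(
                    ped.fid,
                    ind.iid,
                    f"genotype {ind.genotype} incompatible with parents",
                )
            )
    return out
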
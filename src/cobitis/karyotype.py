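"""Additive karyotype arithmetic and GISH-based parental-set assignment.

Hybrid spined loaches (*Cobitis*) carry unrecombined combinations of the
haploid chromosome sets of their sexual progenitors, abbreviated E
(*C. elongatoides*), T (*C. taenia*) and N (*C. tanaitica*).  Each haploid
complement is summarised by chromosome counts in the four Levan morphology
classes (metacentric, submetacentric, subtelocentric, acrocentric).  If
hybrid karyotypes are strictly additive, the per-category counts of a
biotype such as EEN are the sums over its genome letters; genomic in situ
hybridization (GISH) paints each chromosome with two whole-genome probes,
and the per-chromosome two-channel signal ratio assigns it to one parental
set.  This module implements that arithmetic and the ratio classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

GENOME_CODES = ("E", "T", "N")
CATEGORIES = ("meta", "submeta", "subtelo", "acro")

_CATEGORY_ROW_LABELS = {
    "metacentric": "meta",
    "submetacentric": "submeta",
    "subtelocentric": "subtelo",
    "acrocentric": "acro",
}


@dataclass(frozen=True)
class Karyotype:
    """Chromosome counts in the four Levan morphology categories."""

    meta: int = 0
    submeta: int = 0
    subtelo: int = 0
    acro: int = 0

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            v = getattr(self, cat)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"category {cat!r} must be a non-negative integer, got {v!r}")

    def total(self) -> int:
        return self.meta + self.submeta + self.subtelo + self.acro

    def __add__(self, other: "Karyotype") -> "Karyotype":
        return Karyotype(
            self.meta + other.meta,
            self.submeta + other.submeta,
            self.subtelo + other.subtelo,
            self.acro + other.acro,
        )

    def as_dict(self) -> dict[str, int]:
        return {cat: getattr(self, cat) for cat in CATEGORIES}


@dataclass(frozen=True)
class GishChromosome:
    """One chromosome scored after a two-channel GISH experiment.

    ``green_fraction`` is the green channel's share of the total two-channel
    signal on that chromosome (1.0 = pure green probe, 0.0 = pure red).
    """

    category: str
    green_fraction: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown chromosome category {self.category!r}; expected one of {CATEGORIES}")
        if not 0.0 <= self.green_fraction <= 1.0:
            raise ValueError(f"green_fraction must lie in [0, 1], got {self.green_fraction}")


def parse_composition(comp: str) -> str:
    """Validate a genome composition string such as ``"EEN"``.

    Letters are restricted to the three parental codes; length 1-3
    (haploid, diploid or triploid).  The empty string is allowed and
    denotes the empty (all-zero) composition.
    """
    comp = comp.strip().upper()
    for letter in comp:
        if letter not in GENOME_CODES:
            raise ValueError(f"unknown genome code {letter!r} in composition {comp!r}; expected letters from {GENOME_CODES}")
    if len(comp) > 3:
        raise ValueError(f"composition {comp!r} longer than triploid (3 letters)")
    return comp


def load_reference_table(path: str | Path | None = None) -> dict[str, Karyotype]:
    """Load the reference karyotype table (genome code -> Karyotype).

    The packaged fixture transcribes the published per-genome category
    counts; ``-`` entries mean zero.  A ``total`` row, when present, is
    checked against the recomputed category sum.
    """
    if path is None:
        src = resources.files("cobitis").joinpath("data/table1_karyotypes.tsv")
        text = src.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[0] != "category":
        raise ValueError("reference karyotype table must start with a 'category' column")
    codes = header[1:]
    rows: dict[str, list[int]] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        label = parts[0]
        vals = [0 if p.strip() == "-" else int(p) for p in parts[1:]]
        if len(vals) != len(codes):
            raise ValueError(f"row {label!r} has {len(vals)} values for {len(codes)} genome codes")
        rows[label] = vals
    missing = set(_CATEGORY_ROW_LABELS) - set(rows)
    if missing:
        raise ValueError(f"reference table missing category rows: {sorted(missing)}")
    table: dict[str, Karyotype] = {}
    for j, code in enumerate(codes):
        kt = Karyotype(
            meta=rows["metacentric"][j],
            submeta=rows["submetacentric"][j],
            subtelo=rows["subtelocentric"][j],
            acro=rows["acrocentric"][j],
        )
        if "total" in rows and rows["total"][j] != kt.total():
            raise ValueError(
                f"column {code!r}: printed total {rows['total'][j]} != category sum {kt.total()}"
            )
        table[code] = kt
    return table


def haploid_karyotype(code: str, table: Mapping[str, Karyotype]) -> Karyotype:
    """Haploid category counts for one parental genome letter."""
    code = code.strip().upper()
    if code not in GENOME_CODES:
        raise ValueError(f"unknown genome code {code!r}; expected one of {GENOME_CODES}")
    if code not in table:
        raise ValueError(f"genome code {code!r} not present in the reference table")
    return table[code]


def compose_karyotype(comp: str, table: Mapping[str, Karyotype]) -> Karyotype:
    """Expected hybrid karyotype: per-category sums of the letters' haploid sets."""
    comp = parse_composition(comp)
    out = Karyotype()
    for letter in comp:
        out = out + haploid_karyotype(letter, table)
    return out


@dataclass(frozen=True)
class AdditivityReport:
    """Observed minus expected per category for one genome composition."""

    composition: str
    observed: Karyotype
    expected: Karyotype
    differences: dict[str, int] = field(default_factory=dict)

    @property
    def consistent(self) -> bool:
        return all(d == 0 for d in self.differences.values())


def verify_additivity(observed: Karyotype, comp: str, table: Mapping[str, Karyotype]) -> AdditivityReport:
    """Compare an observed karyotype with the additive expectation for ``comp``."""
    expected = compose_karyotype(comp, table)
    diffs = {cat: getattr(observed, cat) - getattr(expected, cat) for cat in CATEGORIES}
    return AdditivityReport(parse_composition(comp), observed, expected, diffs)


@dataclass(frozen=True)
class GishAssignment:
    """Per-set category counts from a two-channel GISH classification.

    Chromosomes whose green fraction falls inside the dead zone around the
    threshold are reported as ambiguous, never force-assigned: balanced
    signals are treated as non-specific hybridization noise rather than
    evidence of recombination.
    """

    green: Karyotype
    red: Karyotype
    ambiguous: Karyotype
    threshold: float
    dead_zone: float

    def conserved_total(self) -> int:
        return self.green.total() + self.red.total() + self.ambiguous.total()


def assign_parental_sets(
    chromosomes: Iterable[GishChromosome],
    threshold: float = 0.5,
    dead_zone: float = 0.0,
) -> GishAssignment:
    """Assign each chromosome to the green- or red-probed parental set.

    A chromosome goes to the green set iff ``green_fraction > threshold +
    dead_zone``, to the red set iff ``green_fraction < threshold -
    dead_zone``, and to the ambiguous pile otherwise (including exact
    threshold hits).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if dead_zone < 0.0:
        raise ValueError(f"dead_zone must be >= 0, got {dead_zone}")
    counts = {"green": dict.fromkeys(CATEGORIES, 0),
              "red": dict.fromkeys(CATEGORIES, 0),
              "ambiguous": dict.fromkeys(CATEGORIES, 0)}
    for chrom in chromosomes:
        if chrom.green_fraction > threshold + dead_zone:
            side = "green"
        elif chrom.green_fraction < threshold - dead_zone:
            side = "red"
        else:
            side = "ambiguous"
        counts[side][chrom.category] += 1
    return GishAssignment(
        green=Karyotype(**counts["green"]),
        red=Karyotype(**counts["red"]),
        ambiguous=Karyotype(**counts["ambiguous"]),
        threshold=threshold,
        dead_zone=dead_zone,
    )
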
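"""Sampling-design table: individuals, metaphases and GISH experiments per biotype.

The study design is a per-locality table: biotype (genome composition),
country, locality, coordinates, age class of the clone (F1, B1, Holocene,
hybrid clade I, or none for the sexual parentals), and four counts —
individuals (NOI), metaphases karyologically analysed (NOMKA), GISH
experiments (NOGE) and analysed GISH metaphases (NOAGM).  Printed "total"
rows are never trusted: they are excluded on load and recomputed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .karyotype import parse_composition

AGE_CLASSES = ("F1", "B1", "Holocene", "hybrid clade I", "none")

_AGE_CLASS_ALIASES = {
    "f1 generation": "F1",
    "f1": "F1",
    "b1 generation": "B1",
    "b1": "B1",
    "holocene": "Holocene",
    "hybrid clade i": "hybrid clade I",
    "-": "none",
    "": "none",
    "none": "none",
}

COUNT_COLUMNS = ("noi", "nomka", "noge", "noagm")


@dataclass(frozen=True)
class CohortRecord:
    biotype: str
    country: str
    locality: str
    lat: str
    long: str
    age_class: str
    noi: int
    probe_donors: int            # individuals marked '*' (GISH probe gDNA donors)
    nomka: Optional[int]         # None = printed as absent ('-')
    noge: Optional[int]
    noagm: Optional[int]

    def is_hybrid(self) -> bool:
        return len(set(self.biotype)) > 1

    def count(self, column: str) -> int:
        v = getattr(self, column)
        return 0 if v is None else v


_NOI_TOKEN = re.compile(r"^(\d+)(\*?)$")


def _parse_noi(raw: str, where: str) -> tuple[int, int]:
    """Parse an individuals entry such as '1', '2*' or '2* + 1'.

    Returns (total individuals, probe donors).  Starred individuals donated
    genomic DNA for GISH probes and count toward NOI exactly as printed.
    """
    total = donors = 0
    for token in raw.split("+"):
        token = token.strip()
        m = _NOI_TOKEN.match(token)
        if not m:
            raise ValueError(f"{where}: cannot parse individuals entry {raw!r}")
        k = int(m.group(1))
        total += k
        if m.group(2):
            donors += k
    return total, donors


def _parse_count(raw: str, column: str, where: str) -> Optional[int]:
    raw = raw.strip()
    if raw in ("-", ""):
        return None
    try:
        v = int(raw)
    except ValueError:
        raise ValueError(f"{where}: column {column!r} value {raw!r} is not an integer") from None
    if v < 0:
        raise ValueError(f"{where}: column {column!r} must be non-negative, got {v}")
    return v


EXPECTED_HEADER = ["biotype", "country", "locality", "lat", "long", "aoc",
                   "noi", "nomka", "noge", "noagm"]


def load_cohort(path: str | Path | None = None) -> list[CohortRecord]:
    """Load locality-level cohort records from a TSV file.

    ``path=None`` loads the packaged study-design fixture.  Rows whose
    biotype or country field reads ``total`` are skipped (totals are
    recomputed by :func:`aggregate_cohort`).  Malformed rows are rejected
    with their 1-based line number.
    """
    if path is None:
        src = resources.files("cobitis").joinpath("data/table2_cohort.tsv")
        text = src.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        return []
    header = [h.strip().lower() for h in lines[0].split("\t")]
    if header != EXPECTED_HEADER:
        raise ValueError(f"cohort header {header} does not match expected schema {EXPECTED_HEADER}")
    records: list[CohortRecord] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if parts[0].strip().lower() == "total" or (len(parts) > 1 and parts[1].strip().lower() == "total"):
            continue
        if len(parts) != len(EXPECTED_HEADER):
            raise ValueError(f"row {lineno}: expected {len(EXPECTED_HEADER)} columns, got {len(parts)}")
        where = f"row {lineno}"
        biotype = parse_composition(parts[0])
        age_key = parts[5].strip().lower()
        if age_key not in _AGE_CLASS_ALIASES:
            raise ValueError(f"{where}: unknown age class {parts[5]!r}")
        age_class = _AGE_CLASS_ALIASES[age_key]
        noi, donors = _parse_noi(parts[6], where)
        rec = CohortRecord(
            biotype=biotype,
            country=parts[1].strip(),
            locality=parts[2].strip(),
            lat=parts[3].strip(),
            long=parts[4].strip(),
            age_class=age_class,
            noi=noi,
            probe_donors=donors,
            nomka=_parse_count(parts[7], "nomka", where),
            noge=_parse_count(parts[8], "noge", where),
            noagm=_parse_count(parts[9], "noagm", where),
        )
        if rec.age_class == "none" and rec.is_hybrid():
            raise ValueError(f"{where}: hybrid biotype {rec.biotype} must carry an age class")
        records.append(rec)
    return records


def aggregate_cohort(records: Iterable[CohortRecord], group_by: str = "biotype") -> dict[str, dict[str, int]]:
    """Exact integer totals of NOI/NOMKA/NOGE/NOAGM per group.

    ``group_by`` is ``"biotype"``, ``"age_class"`` or ``"all-hybrids"``
    (a single group excluding the sexual parental biotypes EE/TT/NN).
    Absent counts ('-') contribute zero to sums.
    """
    records = list(records)
    if group_by == "all-hybrids":
        groups = {"all-hybrids": [r for r in records if r.is_hybrid()]}
    elif group_by in ("biotype", "age_class"):
        groups: dict[str, list[CohortRecord]] = {}
        for r in records:
            groups.setdefault(getattr(r, group_by), []).append(r)
    else:
        raise ValueError(f"unknown group_by {group_by!r}; expected 'biotype', 'age_class' or 'all-hybrids'")
    out: dict[str, dict[str, int]] = {}
    for key, rs in groups.items():
        out[key] = {col: sum(r.count(col) for r in rs) for col in COUNT_COLUMNS}
        out[key]["probe_donors"] = sum(r.probe_donors for r in rs)
        out[key]["n_localities"] = len(rs)
    return out
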
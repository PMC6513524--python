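"""Coat-protein / VLP property records and their aggregate statistics.

The packaged fixture ``data/table1.tsv`` is a transcription of the published
property table of 110 experimentally studied metagenomic ssRNA phage coat
proteins plus six previously studied reference phages (MS2, Qβ, PRR1, PP7,
AP205, Cb5); transcription choices are documented in
``data/table1_errata.md``.  Aggregates are computed over the non-reference
rows: construct count, VLP formation count, low-temperature solubility
rescue, thermal-stability distribution, disulfide classes, and the
length/Tm extremes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

_TR = {"++": "confirmed", "+": "predicted", "": "none", "n.d.": "nd"}
_SS = {
    "56": "pent_hex",
    "5": "pent_only",
    "D": "dimer",
    "N": "none_detected",
    "": "nd",
    "n.d.": "nd",
}
_PRODUCTION = {
    "+++": "high",
    "++": "average",
    "+": "low",
    "+/-": "very_low",
    "-": "none",
}
_SOLUBILITY = {
    "+++": "high",
    "++": "ge50",
    "+": "lt50",
    "+/-": "very_low",
    "-": "none",
    "n.d.": "nd",
    "n/a": "nd",
}
_VLP_EM = {
    "+++": "high",
    "++": "good",
    "+": "some",
    "-": "none",
    "n.d.": "nd",
    "n/a": "nd",
}

#: Solubility categories that count as "at least partially soluble".
SOLUBLE_CATEGORIES = frozenset({"high", "ge50", "lt50", "very_low"})


@dataclass(frozen=True)
class CpPropertyRow:
    """One property-table record for a coat protein / VLP."""

    name: str
    group: str
    length: int
    cysteine_positions: tuple[int, ...]
    ss_class: str
    tr_flag: str
    production: str
    solubility_37: str
    solubility_15: str
    vlp_em: str
    morphology: str | None
    diameter_nm: float | None
    tm_c: float | None
    is_reference: bool

    def __post_init__(self) -> None:
        if list(self.cysteine_positions) != sorted(self.cysteine_positions):
            raise ValueError(f"{self.name}: cysteine positions not sorted")
        if any(p < 1 or p > self.length for p in self.cysteine_positions):
            raise ValueError(
                f"{self.name}: cysteine position outside chain length"
            )
        if self.tm_c is not None and not 20 <= self.tm_c <= 100:
            raise ValueError(f"{self.name}: Tm {self.tm_c} outside [20, 100]")

    @property
    def forms_vlps(self) -> bool:
        return self.vlp_em not in ("none", "nd")


@dataclass(frozen=True)
class SummaryStats:
    """The table-level aggregate statistics."""

    n_constructs: int
    n_vlp_forming: int
    pct_tm_50_70: int
    n_insoluble_at_15: int
    pct_rescued_at_15: int
    n_pent_hex_disulfide: int
    tm_min: float
    tm_max: float
    len_min: int
    len_max: int

    def to_dict(self) -> dict[str, float | int]:
        return {
            "n_constructs": self.n_constructs,
            "n_vlp_forming": self.n_vlp_forming,
            "pct_tm_50_70": self.pct_tm_50_70,
            "n_insoluble_at_15": self.n_insoluble_at_15,
            "pct_rescued_at_15": self.pct_rescued_at_15,
            "n_pent_hex_disulfide": self.n_pent_hex_disulfide,
            "tm_min": self.tm_min,
            "tm_max": self.tm_max,
            "len_min": self.len_min,
            "len_max": self.len_max,
        }


def packaged_table_path() -> Path:
    """Path to the packaged property-table fixture."""
    return Path(resources.files("levikit") / "data" / "table1.tsv")


def _map_token(mapping: dict[str, str], token: str, row: str, col: str) -> str:
    token = token.strip()
    if token not in mapping:
        raise ValueError(f"row {row!r}: unknown {col} token {token!r}")
    return mapping[token]


def _parse_positions(token: str, row: str) -> tuple[int, ...]:
    token = token.strip()
    if token in ("", "n.d.", "n/a"):
        return ()
    try:
        return tuple(sorted(int(p) for p in token.replace(" ", "").split(",")))
    except ValueError as exc:
        raise ValueError(
            f"row {row!r}: unparseable cysteine positions {token!r}"
        ) from exc


def _parse_number(token: str, row: str, col: str) -> float | None:
    token = token.strip()
    if token in ("", "n.d.", "n/a"):
        return None
    try:
        return float(token)
    except ValueError as exc:
        raise ValueError(f"row {row!r}: unparseable {col} {token!r}") from exc


def load_table(path: str | Path | None = None) -> list[CpPropertyRow]:
    """Load and validate a property table TSV (the packaged one by default)."""
    if path is None:
        path = packaged_table_path()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {
        "name", "group", "length", "cysteines", "ss", "tr", "production",
        "sol_37", "sol_15", "vlp_em", "morphology", "diameter_nm", "tm_c",
        "reference",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    rows: list[CpPropertyRow] = []
    names: set[str] = set()
    for record in df.to_dict(orient="records"):
        name = record["name"].strip()
        if name in names:
            raise ValueError(f"duplicate row name {name!r}")
        names.add(name)
        morphology = record["morphology"].strip()
        rows.append(
            CpPropertyRow(
                name=name,
                group=record["group"].strip(),
                length=int(record["length"]),
                cysteine_positions=_parse_positions(record["cysteines"], name),
                ss_class=_map_token(_SS, record["ss"], name, "ss"),
                tr_flag=_map_token(_TR, record["tr"], name, "tr"),
                production=_map_token(
                    _PRODUCTION, record["production"], name, "production"
                ),
                solubility_37=_map_token(
                    _SOLUBILITY, record["sol_37"], name, "sol_37"
                ),
                solubility_15=_map_token(
                    _SOLUBILITY, record["sol_15"], name, "sol_15"
                ),
                vlp_em=_map_token(_VLP_EM, record["vlp_em"], name, "vlp_em"),
                morphology=morphology if morphology not in ("", "n/a") else None,
                diameter_nm=_parse_number(record["diameter_nm"], name, "diameter"),
                tm_c=_parse_number(record["tm_c"], name, "tm"),
                is_reference=record["reference"].strip() in ("1", "true", "yes"),
            )
        )
    return rows


def disulfide_candidates(
    row: CpPropertyRow,
    spacing_max: int = 8,
    central_fraction: float = 0.6,
) -> tuple[bool, str]:
    """Screen cysteine placement for inter-subunit disulfide candidacy.

    The experimentally confirmed disulfide-bonded coat proteins carry
    closely spaced cysteines approximately in the middle of the chain.  A
    row is a candidate iff at least two cysteines lie within the central
    ``central_fraction`` of the chain and some pair of them is at most
    ``spacing_max`` residues apart.
    """
    if not 0 < central_fraction <= 1:
        raise ValueError("central_fraction must lie in (0, 1]")
    margin = (1.0 - central_fraction) / 2.0
    lo = margin * row.length
    hi = (1.0 - margin) * row.length
    central = [p for p in row.cysteine_positions if lo <= p <= hi]
    if len(central) < 2:
        reason = (
            "fewer than two cysteines"
            if len(row.cysteine_positions) < 2
            else f"fewer than two cysteines in the central band [{lo:.1f}, {hi:.1f}]"
        )
        return False, reason
    for a, b in zip(central, central[1:]):
        if b - a <= spacing_max:
            return True, (
                f"cysteines {a} and {b} are {b - a} apart within the central "
                f"band [{lo:.1f}, {hi:.1f}]"
            )
    return False, f"no central cysteine pair within {spacing_max} residues"


def _round_half_up(value: float) -> int:
    """Round half away from zero (matches the table's percentage style)."""
    return int(math.floor(value + 0.5)) if value >= 0 else -int(
        math.floor(-value + 0.5)
    )


def summarize(rows: Sequence[CpPropertyRow]) -> SummaryStats:
    """Aggregate statistics over the non-reference rows.

    The rescue percentage is computed over proteins completely insoluble at
    37 °C whose 15 °C outcome was recorded; "soluble" means any category
    except none/n.d.
    """
    novel = [r for r in rows if not r.is_reference]
    if not novel:
        raise ValueError("no non-reference rows to summarize")
    n_constructs = len(novel)
    n_vlp = sum(r.forms_vlps for r in novel)
    insoluble_37 = [r for r in novel if r.solubility_37 == "none"]
    tested_15 = [r for r in insoluble_37 if r.solubility_15 != "nd"]
    rescued = [r for r in tested_15 if r.solubility_15 in SOLUBLE_CATEGORIES]
    n_insoluble_15 = sum(r.solubility_15 == "none" for r in tested_15)
    pct_rescued = (
        _round_half_up(100.0 * len(rescued) / len(tested_15)) if tested_15 else 0
    )
    tms = [r.tm_c for r in novel if r.tm_c is not None]
    if not tms:
        raise ValueError("no numeric Tm values present")
    pct_tm = _round_half_up(
        100.0 * sum(50 <= t <= 70 for t in tms) / len(tms)
    )
    return SummaryStats(
        n_constructs=n_constructs,
        n_vlp_forming=n_vlp,
        pct_tm_50_70=pct_tm,
        n_insoluble_at_15=n_insoluble_15,
        pct_rescued_at_15=pct_rescued,
        n_pent_hex_disulfide=sum(r.ss_class == "pent_hex" for r in novel),
        tm_min=min(tms),
        tm_max=max(tms),
        len_min=min(r.length for r in novel),
        len_max=max(r.length for r in novel),
    )
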
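"""Domain types for substances and tabular I/O.

A substance record collects identity, physico-chemical properties,
toxicity, bioaccumulation and use data for one chemical.  Data are
routinely sparse: every field that may be missing is represented by
``None`` (for scalars) or an empty list, never by zero.  Flags that can
be true, false or unresolved are tri-state ``Optional[bool]`` values
where ``None`` means "unknown".

Tables are plain CSV (UTF-8, comma separated, ``.`` decimal; TSV via
``delimiter="\\t"``).  List-valued cells use ``;`` as the inner
separator, and registry volumes-per-year use ``year:tonnes`` pairs,
e.g. ``2006:10;2007:30``.  Unknown columns are carried through
untouched in ``SubstanceRecord.extra``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "SubstanceRecord",
    "PropertySet",
    "ToxicityDataset",
    "ToxValue",
    "BioaccumulationData",
    "UseData",
    "ProductionRecord",
    "ValidationReport",
    "ValidationIssue",
    "TableFormatError",
    "validate_cas",
    "validate_record",
    "records_from_dataframe",
    "read_substance_table",
    "write_substance_table",
    "write_ranked_table",
    "SUBSTANCE_COLUMNS",
    "USE_CATEGORIES",
]

# Closed vocabulary of use-pattern categories (dispersiveness classes).
USE_CATEGORIES = (
    "controlled_intermediate",
    "industrial_nondispersive_or_matrix",
    "wide_dispersive",
    "environmental_use",
    "pesticide",
    "cosmetic",
    "pharmaceutical",
)

TAXA = ("fish", "invertebrate", "algae", "other")

_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")


class TableFormatError(ValueError):
    """A substance table violates the documented column contract."""


def validate_cas(cas: str) -> bool:
    """Check a CAS registry number's format and check digit.

    The check digit is the weighted sum of the other digits, taken
    right to left with weights 1, 2, 3, ..., modulo 10.  Malformed
    input returns ``False`` rather than raising.
    """
    if not isinstance(cas, str):
        return False
    m = _CAS_RE.match(cas.strip())
    if not m:
        return False
    digits = (m.group(1) + m.group(2))[::-1]
    checksum = sum((i + 1) * int(d) for i, d in enumerate(digits)) % 10
    return checksum == int(m.group(3))


@dataclass
class PropertySet:
    """Physico-chemical properties; all half-lives in days."""

    mw: Optional[float] = None            # g/mol
    log_kow: Optional[float] = None
    log_kaw: Optional[float] = None       # air-water (Henry-law derived)
    t_half_water: Optional[float] = None
    t_half_sediment: Optional[float] = None
    t_half_soil: Optional[float] = None
    t_half_air: Optional[float] = None
    biowin3: Optional[float] = None       # ultimate-biodegradation survey score, 0-5
    biowin6: Optional[float] = None       # probability of fast biodegradation, 0-1
    marine_water: bool = False            # half-life refers to marine medium
    marine_sediment: bool = False


@dataclass
class ToxValue:
    taxon: str                            # fish | invertebrate | algae | other
    value: float                          # mg/L
    source: str = "experimental"          # experimental | qsar


@dataclass
class ToxicityDataset:
    chronic_noecs: list[ToxValue] = field(default_factory=list)
    acute_ec50s: list[ToxValue] = field(default_factory=list)
    qsar_t_votes: list[bool] = field(default_factory=list)
    carcinogen_cat: Optional[int] = None
    mutagen_cat: Optional[int] = None
    repro_cat: Optional[int] = None
    r48_t: bool = False                   # T;R48 chronic classification
    r48_xn: bool = False                  # Xn;R48

    def experimental_acute(self) -> list[ToxValue]:
        return [v for v in self.acute_ec50s if v.source == "experimental"]

    def qsar_acute(self) -> list[ToxValue]:
        return [v for v in self.acute_ec50s if v.source == "qsar"]


@dataclass
class BioaccumulationData:
    bcf_experimental: Optional[float] = None      # L/kg
    bcf_predictions: list[float] = field(default_factory=list)
    bmf_chain: list[float] = field(default_factory=list)


@dataclass
class ProductionRecord:
    source: str                           # iuclid-like | spin-like
    tonnage: float                        # t/y


@dataclass
class UseData:
    production_records: list[ProductionRecord] = field(default_factory=list)
    use_entries: list[str] = field(default_factory=list)
    spin_volumes: dict[int, float] = field(default_factory=dict)  # year -> tonnes


@dataclass
class SubstanceRecord:
    cas: str
    name: str = ""
    smiles: Optional[str] = None
    props: PropertySet = field(default_factory=PropertySet)
    tox: ToxicityDataset = field(default_factory=ToxicityDataset)
    bioacc: BioaccumulationData = field(default_factory=BioaccumulationData)
    use: UseData = field(default_factory=UseData)
    ed_flag: Optional[bool] = None        # endocrine-disruptor list membership
    extra: dict[str, str] = field(default_factory=dict)


@dataclass
class ValidationIssue:
    field: str
    severity: str                         # error | warning
    message: str


@dataclass
class ValidationReport:
    record_id: str
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)


def validate_record(record: SubstanceRecord) -> ValidationReport:
    """Validate one record; an empty issue list means fully usable."""
    report = ValidationReport(record_id=record.cas)

    def err(fld: str, msg: str) -> None:
        report.issues.append(ValidationIssue(fld, "error", msg))

    if not validate_cas(record.cas):
        err("cas", f"invalid CAS registry number: {record.cas!r}")
    p = record.props
    for fld in ("t_half_water", "t_half_sediment", "t_half_soil", "t_half_air"):
        v = getattr(p, fld)
        if v is not None and v <= 0:
            err(fld, "half-life must be strictly positive")
    if p.mw is not None and p.mw <= 0:
        err("mw", "molecular weight must be positive")
    if p.biowin6 is not None and not (0.0 <= p.biowin6 <= 1.0):
        err("biowin6", "biodegradation probability must lie in [0, 1]")
    for group, vals in (("chronic_noecs", record.tox.chronic_noecs),
                        ("acute_ec50s", record.tox.acute_ec50s)):
        for v in vals:
            if v.value <= 0:
                err(group, "concentrations must be positive (mg/L)")
            if v.taxon not in TAXA:
                err(group, f"unknown taxon {v.taxon!r}")
            if v.source not in ("experimental", "qsar"):
                err(group, f"unknown source {v.source!r}")
    if record.bioacc.bcf_experimental is not None and record.bioacc.bcf_experimental <= 0:
        err("bcf_experimental", "BCF must be positive")
    if any(b <= 0 for b in record.bioacc.bcf_predictions):
        err("bcf_predictions", "BCF must be positive")
    if any(b <= 0 for b in record.bioacc.bmf_chain):
        err("bmf_chain", "BMF must be positive")
    for rec in record.use.production_records:
        if rec.tonnage < 0:
            err("production_records", "tonnage must be non-negative")
        if rec.source not in ("iuclid-like", "spin-like"):
            err("production_records", f"unknown source {rec.source!r}")
    for entry in record.use.use_entries:
        if entry not in USE_CATEGORIES:
            err("use_entries", f"unknown use category {entry!r}")
    if any(v < 0 for v in record.use.spin_volumes.values()):
        err("spin_volumes", "registry volumes must be non-negative")
    return report


# ---------------------------------------------------------------------------
# Tabular I/O

# Documented column vocabulary, in canonical order.
SUBSTANCE_COLUMNS = (
    "cas", "name", "smiles",
    "mw", "log_kow", "log_kaw",
    "t_half_water", "t_half_sediment", "t_half_soil", "t_half_air",
    "marine_water", "marine_sediment",
    "biowin3", "biowin6",
    "bcf_experimental", "bcf_predictions", "bmf_chain",
    "noec_fish", "noec_invertebrate", "noec_algae", "noec_other",
    "ec50_fish", "ec50_invertebrate", "ec50_algae", "ec50_other",
    "qsar_ec50s", "qsar_t_votes",
    "carcinogen_cat", "mutagen_cat", "repro_cat", "r48_t", "r48_xn",
    "ed_flag",
    "tonnage_iuclid", "spin_volumes", "use_entries",
)

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


def _cell(row: pd.Series, col: str) -> Optional[str]:
    if col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    s = str(v).strip()
    return s if s else None


def _as_float(s: Optional[str]) -> Optional[float]:
    return None if s is None else float(s)


def _as_int(s: Optional[str]) -> Optional[int]:
    return None if s is None else int(float(s))


def _as_bool(s: Optional[str], default: Optional[bool] = None) -> Optional[bool]:
    if s is None:
        return default
    low = s.lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise TableFormatError(f"cannot interpret {s!r} as a boolean")


def _float_list(s: Optional[str]) -> list[float]:
    if s is None:
        return []
    return [float(tok) for tok in s.split(";") if tok.strip()]


def _str_list(s: Optional[str]) -> list[str]:
    if s is None:
        return []
    return [tok.strip() for tok in s.split(";") if tok.strip()]


def _vote_list(s: Optional[str]) -> list[bool]:
    out = []
    for tok in _str_list(s):
        b = _as_bool(tok)
        if b is None:
            raise TableFormatError(f"cannot interpret QSAR vote {tok!r}")
        out.append(b)
    return out


def _year_map(s: Optional[str]) -> dict[int, float]:
    out: dict[int, float] = {}
    for tok in _str_list(s):
        if ":" not in tok:
            raise TableFormatError(
                f"registry volume entry {tok!r} is not of the form year:tonnes")
        year, vol = tok.split(":", 1)
        out[int(year)] = float(vol)
    return out


def _record_from_row(row: pd.Series, known: set[str]) -> SubstanceRecord:
    cas = _cell(row, "cas")
    if cas is None:
        raise TableFormatError("row with empty 'cas' cell")
    props = PropertySet(
        mw=_as_float(_cell(row, "mw")),
        log_kow=_as_float(_cell(row, "log_kow")),
        log_kaw=_as_float(_cell(row, "log_kaw")),
        t_half_water=_as_float(_cell(row, "t_half_water")),
        t_half_sediment=_as_float(_cell(row, "t_half_sediment")),
        t_half_soil=_as_float(_cell(row, "t_half_soil")),
        t_half_air=_as_float(_cell(row, "t_half_air")),
        biowin3=_as_float(_cell(row, "biowin3")),
        biowin6=_as_float(_cell(row, "biowin6")),
        marine_water=bool(_as_bool(_cell(row, "marine_water"), default=False)),
        marine_sediment=bool(_as_bool(_cell(row, "marine_sediment"), default=False)),
    )
    tox = ToxicityDataset(
        qsar_t_votes=_vote_list(_cell(row, "qsar_t_votes")),
        carcinogen_cat=_as_int(_cell(row, "carcinogen_cat")),
        mutagen_cat=_as_int(_cell(row, "mutagen_cat")),
        repro_cat=_as_int(_cell(row, "repro_cat")),
        r48_t=bool(_as_bool(_cell(row, "r48_t"), default=False)),
        r48_xn=bool(_as_bool(_cell(row, "r48_xn"), default=False)),
    )
    for taxon in TAXA:
        v = _as_float(_cell(row, f"noec_{taxon}"))
        if v is not None:
            tox.chronic_noecs.append(ToxValue(taxon, v, "experimental"))
        v = _as_float(_cell(row, f"ec50_{taxon}"))
        if v is not None:
            tox.acute_ec50s.append(ToxValue(taxon, v, "experimental"))
    for v in _float_list(_cell(row, "qsar_ec50s")):
        tox.acute_ec50s.append(ToxValue("other", v, "qsar"))
    bioacc = BioaccumulationData(
        bcf_experimental=_as_float(_cell(row, "bcf_experimental")),
        bcf_predictions=_float_list(_cell(row, "bcf_predictions")),
        bmf_chain=_float_list(_cell(row, "bmf_chain")),
    )
    use = UseData(
        use_entries=_str_list(_cell(row, "use_entries")),
        spin_volumes=_year_map(_cell(row, "spin_volumes")),
    )
    for t in _float_list(_cell(row, "tonnage_iuclid")):
        use.production_records.append(ProductionRecord("iuclid-like", t))
    extra = {c: str(row[c]) for c in row.index
             if c not in known and _cell(row, c) is not None}
    return SubstanceRecord(
        cas=cas,
        name=_cell(row, "name") or "",
        smiles=_cell(row, "smiles"),
        props=props,
        tox=tox,
        bioacc=bioacc,
        use=use,
        ed_flag=_as_bool(_cell(row, "ed_flag")),
        extra=extra,
    )


def records_from_dataframe(df: pd.DataFrame) -> list[SubstanceRecord]:
    """Convert a substance-table DataFrame (string cells) to records.

    Duplicate CAS rows are rejected: conflicting duplicates from merged
    source lists must be reconciled upstream.
    """
    if "cas" not in df.columns:
        raise TableFormatError("mandatory column 'cas' is missing")
    records = [_record_from_row(row, set(SUBSTANCE_COLUMNS)) for _, row in df.iterrows()]
    seen: dict[str, int] = {}
    for i, r in enumerate(records):
        if r.cas in seen:
            raise TableFormatError(
                f"duplicate CAS {r.cas} at rows {seen[r.cas]} and {i}: "
                "reconcile duplicates before loading")
        seen[r.cas] = i
    return records


def read_substance_table(path: str | Path, delimiter: str = ",") -> list[SubstanceRecord]:
    """Read a substance table; one record per row, row order preserved.

    Missing cells become absent-valued fields, never zeros.  A missing
    ``cas`` column raises :class:`TableFormatError`.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=True)
    df.columns = [str(c).strip() for c in df.columns]
    return records_from_dataframe(df)


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float) and float(v).is_integer() and abs(v) < 1e15:
        return str(int(v))
    return str(v)


def _row_from_record(r: SubstanceRecord) -> dict[str, str]:
    row = {c: "" for c in SUBSTANCE_COLUMNS}
    row["cas"] = r.cas
    row["name"] = r.name
    row["smiles"] = _fmt(r.smiles)
    p = r.props
    for fld in ("mw", "log_kow", "log_kaw", "t_half_water", "t_half_sediment",
                "t_half_soil", "t_half_air", "biowin3", "biowin6"):
        row[fld] = _fmt(getattr(p, fld))
    row["marine_water"] = _fmt(p.marine_water)
    row["marine_sediment"] = _fmt(p.marine_sediment)
    row["bcf_experimental"] = _fmt(r.bioacc.bcf_experimental)
    row["bcf_predictions"] = ";".join(_fmt(v) for v in r.bioacc.bcf_predictions)
    row["bmf_chain"] = ";".join(_fmt(v) for v in r.bioacc.bmf_chain)
    for taxon in TAXA:
        noecs = [v.value for v in r.tox.chronic_noecs if v.taxon == taxon]
        if noecs:
            row[f"noec_{taxon}"] = _fmt(min(noecs))
        ecs = [v.value for v in r.tox.experimental_acute() if v.taxon == taxon]
        if ecs:
            row[f"ec50_{taxon}"] = _fmt(min(ecs))
    row["qsar_ec50s"] = ";".join(_fmt(v.value) for v in r.tox.qsar_acute())
    row["qsar_t_votes"] = ";".join(_fmt(v) for v in r.tox.qsar_t_votes)
    for fld in ("carcinogen_cat", "mutagen_cat", "repro_cat"):
        row[fld] = _fmt(getattr(r.tox, fld))
    row["r48_t"] = _fmt(r.tox.r48_t)
    row["r48_xn"] = _fmt(r.tox.r48_xn)
    row["ed_flag"] = _fmt(r.ed_flag)
    row["tonnage_iuclid"] = ";".join(
        _fmt(p.tonnage) for p in r.use.production_records if p.source == "iuclid-like")
    row["spin_volumes"] = ";".join(
        f"{y}:{_fmt(v)}" for y, v in sorted(r.use.spin_volumes.items()))
    row["use_entries"] = ";".join(r.use.use_entries)
    for k, v in r.extra.items():
        row[k] = v
    return row


def write_substance_table(records: list[SubstanceRecord], path: str | Path,
                          delimiter: str = ",") -> None:
    rows = [_row_from_record(r) for r in records]
    extra_cols = sorted({k for row in rows for k in row} - set(SUBSTANCE_COLUMNS))
    cols = list(SUBSTANCE_COLUMNS) + extra_cols
    df = pd.DataFrame(rows, columns=cols).fillna("")
    df.to_csv(path, sep=delimiter, index=False)


def write_ranked_table(results, path: str | Path) -> None:
    """Write a ranked-risk CSV (descending ratio, ties by ascending CAS).

    Concentrations are written in scientific notation with 3 significant
    digits; the ratio appears both at full precision and as the rounded
    display value.
    """
    from .risk import display_ratio  # local import to avoid a cycle

    rows = sorted(results, key=lambda r: (-r.ratio, r.cas))
    out = pd.DataFrame(
        [{
            "cas": r.cas,
            "name": r.name,
            "pnec_mg_per_L": f"{r.pnec:.2e}",
            "pec_mg_per_L": f"{r.pec:.2e}",
            "risk_ratio": repr(float(r.ratio)),
            "risk_ratio_display": _fmt(display_ratio(r.ratio)),
        } for r in rows],
        columns=["cas", "name", "pnec_mg_per_L", "pec_mg_per_L",
                 "risk_ratio", "risk_ratio_display"],
    )
    out.to_csv(path, index=False)
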
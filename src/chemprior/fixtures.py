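"""Synthetic substance tables and embedded reference fixtures.

Two sources of test data, neither requiring any download:

* :func:`table6_fixture` — the published ranked list of the 36
  substances whose surface-water risk ratio (PEC/PNEC) exceeded one,
  with their printed PEC and PNEC values (mg/L).  Immutable reference
  data for the risk-characterisation arithmetic and the ranking.
* :func:`generate_substances` — a seeded generator of substance tables
  with controlled data-availability patterns, including planted
  archetypes: known PBT/high-tonnage positives that must surface at
  the top of any correct prioritisation, and known benign chemicals
  that must sink to the lowest priority class.

Synthetic CAS numbers are drawn from a reserved high-numbered block
(first segment 9,0xx,xxx) with valid check digits, so they can never
collide with real registry numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .substances import (SUBSTANCE_COLUMNS, SubstanceRecord, USE_CATEGORIES,
                         records_from_dataframe)

__all__ = ["GeneratorConfig", "generate_substances", "generate_records",
           "synthesize_cas", "table6_fixture", "TABLE6_COLUMNS"]

TABLE6_COLUMNS = ("cas", "name", "pnec_mg_per_L", "pec_mg_per_L")

# Published ranked list: substances with risk ratio PEC/PNEC > 1.
# (CAS, name, PNEC mg/L, PEC mg/L) — values exactly as printed.
_TABLE6 = (
    ("2921-88-2", "chlorpyrifos", 3.00e-6, 1.40e-3),
    ("834-12-8", "ametryn", 3.60e-6, 8.82e-4),
    ("3520-72-7",
     "4,4'-[(3,3'-dichloro[1,1'-biphenyl]-4,4'-diyl)bis(azo)]bis[2,4-dihydro-"
     "5-methyl-2-phenyl-3H-pyrazol-3-one]", 1.97e-5, 3.19e-3),
    ("5567-15-7",
     "2,2'-[(3,3'-dichloro[1,1'-biphenyl]-4,4'-diyl)bis(azo)]bis[N-(4-chloro-"
     "2,5-dimethoxyphenyl)-3-oxobutyramide]", 4.93e-5, 7.48e-3),
    ("5468-75-7",
     "2,2'-[(3,3'-dichloro[1,1'-biphenyl]-4,4'-diyl)bis(azo)]bis[N-(2-"
     "methylphenyl)-3-oxobutyramide]", 3.78e-5, 5.52e-3),
    ("1085-98-9", "dichlofluanide", 1.00e-5, 1.40e-3),
    ("7287-19-6", "prometryn", 2.00e-6, 1.83e-4),
    ("886-50-0", "terbutryn", 2.40e-6, 1.83e-4),
    ("119-47-1", "6,6'-di-tert-butyl-2,2'-methylenedi-p-cresol", 4.49e-5, 3.27e-3),
    ("56-35-9", "bis(tributyltin) oxide", 9.90e-6, 6.92e-4),
    ("5102-83-0",
     "2,2'-[(3,3'-dichloro[1,1'-biphenyl]-4,4'-diyl)bis(azo)]bis[N-(2,4-"
     "dimethylphenyl)-3-oxobutyramide]", 2.81e-5, 1.35e-3),
    ("42576-02-3", "methyl 5-(2,4-dichlorophenoxy)-2-nitrobenzoate", 3.50e-6, 1.25e-4),
    ("79-94-7", "2,2',6,6'-tetrabromo-4,4'-isopropylidenediphenol", 8.45e-5, 2.13e-3),
    ("1897-45-6", "chlorothalonil", 6.00e-5, 1.39e-3),
    ("21725-46-2", "cyanazine", 8.60e-5, 1.96e-3),
    ("67774-74-7", "undecylbenzene", 4.60e-5, 9.69e-4),
    ("50-29-3", "clofenotane", 5.00e-6, 7.12e-5),
    ("74070-46-5", "2-chloro-6-nitro-3-phenoxyaniline", 5.00e-5, 6.84e-4),
    ("1582-09-8", "trifluralin", 4.00e-5, 4.84e-4),
    ("2312-35-8", "propargite", 6.00e-5, 5.77e-4),
    ("67747-09-5",
     "N-propyl-N-[2-(2,4,6-trichlorophenoxy)ethyl]-1H-imidazole-1-carboxamide",
     1.00e-4, 7.45e-4),
    ("115-32-2", "dicofol", 8.80e-5, 5.52e-4),
    ("25637-99-4", "hexabromocyclododecane", 9.68e-5, 5.32e-4),
    ("3194-55-6", "1,2,5,6,9,10-hexabromocyclodecane", 4.86e-4, 2.59e-3),
    ("107-64-2", "dimethyldioctadecylammonium chloride", 1.59e-5, 8.32e-5),
    ("52740-90-6",
     "1-amino-N-(3-bromo-9,10-dihydro-9,10-dioxo-2-anthryl)-9,10-dihydro-"
     "9,10-dioxoanthracene-2-carboxamide", 4.19e-5, 2.17e-4),
    ("32536-52-0", "diphenyl ether, octabromo derivative", 4.75e-5, 2.44e-4),
    ("52315-07-8",
     "alpha-cyano-3-phenoxybenzyl 3-(2,2-dichlorovinyl)-2,2-dimethyl-"
     "cyclopropanecarboxylate", 3.00e-7, 1.38e-6),
    ("68442-68-2", "4-(1-phenylethyl)-N-[4-(1-phenylethyl)phenyl]aniline",
     1.87e-5, 8.16e-5),
    ("96-69-5", "6,6'-di-tert-butyl-4,4'-thiodi-m-cresol", 5.04e-5, 1.85e-4),
    ("55283-68-6", "ethalfluralin", 4.00e-6, 1.22e-5),
    ("1163-19-5", "bis(pentabromophenyl) ether", 4.29e-5, 1.18e-4),
    ("52-68-6", "trichlorfon", 6.00e-5, 1.53e-4),
    ("1912-24-9", "atrazine", 1.30e-3, 3.16e-3),
    ("31570-04-4", "tris(2,4-ditert-butylphenyl) phosphite", 1.67e-5, 3.55e-5),
    ("63449-39-8", "paraffin waxes and hydrocarbon waxes, chloro", 1.67e-4, 2.82e-4),
)


def table6_fixture() -> pd.DataFrame:
    """The published ranked list (36 rows): CAS, name, PNEC, PEC."""
    return pd.DataFrame(list(_TABLE6), columns=TABLE6_COLUMNS)


def synthesize_cas(index: int, middle: int) -> str:
    """Build a valid synthetic CAS number in the reserved 9,0xx,xxx block."""
    if not 0 <= index < 100000:
        raise ValueError("index outside the reserved block")
    body = f"{9000000 + index}{middle % 100:02d}"
    check = sum((i + 1) * int(d) for i, d in enumerate(body[::-1])) % 10
    return f"{9000000 + index}-{middle % 100:02d}-{check}"


@dataclass
class GeneratorConfig:
    """Shape of the synthetic substance population.

    Property distributions are loosely motivated by screening-scale
    chemical inventories (log Kow around 3 with wide spread, water
    half-lives of days to months, tonnages uniform on a log scale from
    1 to 10,000 t/y); they exist to exercise every code path, not to
    replicate any particular inventory.  Availability probabilities
    control how often each data block is present, emulating sparse
    real-world data.
    """

    n: int = 100
    seed: int = 0
    log_kow_mean: float = 3.0
    log_kow_sd: float = 1.5
    log10_t_half_water_mean: float = 1.2   # days
    log10_t_half_water_sd: float = 0.6
    log10_tonnage_min: float = 0.0         # t/y
    log10_tonnage_max: float = 4.0
    p_halflife: float = 0.4
    p_air_halflife: float = 0.8
    p_bcf_experimental: float = 0.6
    p_bcf_predictions: float = 0.6
    p_chronic_noec: float = 0.6
    p_acute_ec50: float = 0.6
    p_qsar_votes: float = 0.6
    p_use: float = 0.6
    p_ed: float = 0.05
    pbt_fraction: float = 0.0      # planted known-positive archetypes
    benign_fraction: float = 0.0   # planted known-negative archetypes


def _pbt_archetype_row(cas: str, i: int) -> dict[str, str]:
    """A guaranteed PBT / high-tonnage substance: long half-lives,
    measured BCF above the very-bioaccumulative limit, chronic NOECs
    far below the toxicity criterion, high production, dispersive use."""
    return {
        "cas": cas, "name": f"planted pbt archetype {i}",
        "mw": "350", "log_kow": "6.5", "log_kaw": "-4",
        "t_half_water": "300", "t_half_sediment": "600",
        "t_half_soil": "300", "t_half_air": "100",
        "bcf_experimental": "6500",
        "noec_fish": "0.0001", "noec_invertebrate": "0.0002", "noec_algae": "0.0003",
        "ed_flag": "false",
        "tonnage_iuclid": "20000",
        "use_entries": "wide_dispersive",
        "archetype": "pbt",
    }


def _benign_archetype_row(cas: str, i: int) -> dict[str, str]:
    """A guaranteed low-priority substance: fast biodegradation, short
    half-lives, low BCF and log Kow, mild toxicity, negligible tonnage
    in a closed use."""
    return {
        "cas": cas, "name": f"planted benign archetype {i}",
        "mw": "150", "log_kow": "2.0", "log_kaw": "-5",
        "t_half_water": "2", "t_half_sediment": "4",
        "t_half_soil": "2", "t_half_air": "0.5",
        "biowin3": "4.5", "biowin6": "0.9",
        "bcf_experimental": "30",
        "noec_fish": "10", "noec_invertebrate": "12", "noec_algae": "15",
        "ec50_fish": "50",
        "ed_flag": "false",
        "tonnage_iuclid": "0.4",
        "use_entries": "controlled_intermediate",
        "archetype": "benign",
    }


def _random_row(cas: str, i: int, cfg: GeneratorConfig,
                rng: np.random.Generator) -> dict[str, str]:
    row: dict[str, str] = {"cas": cas, "name": f"synthetic substance {i}",
                           "archetype": ""}
    log_kow = rng.normal(cfg.log_kow_mean, cfg.log_kow_sd)
    row["mw"] = f"{rng.uniform(80, 600):.1f}"
    row["log_kow"] = f"{log_kow:.3f}"
    row["log_kaw"] = f"{rng.normal(-4.0, 2.0):.3f}"
    # biodegradation-model scores always available (they are predictions)
    row["biowin3"] = f"{rng.uniform(0.5, 5.0):.2f}"
    row["biowin6"] = f"{rng.uniform(0.0, 1.0):.3f}"
    if rng.random() < cfg.p_halflife:
        t_w = 10.0 ** rng.normal(cfg.log10_t_half_water_mean, cfg.log10_t_half_water_sd)
        row["t_half_water"] = f"{t_w:.3f}"
    if rng.random() < cfg.p_air_halflife:
        row["t_half_air"] = f"{10.0 ** rng.normal(0.0, 0.7):.4f}"
    # BCF correlates loosely with hydrophobicity
    log_bcf = 0.65 * log_kow - 0.3
    if rng.random() < cfg.p_bcf_experimental:
        row["bcf_experimental"] = f"{10.0 ** (log_bcf + rng.normal(0, 0.4)):.2f}"
    if rng.random() < cfg.p_bcf_predictions:
        preds = 10.0 ** (log_bcf + rng.normal(0, 0.4, size=3))
        row["bcf_predictions"] = ";".join(f"{v:.2f}" for v in preds)
    if rng.random() < cfg.p_chronic_noec:
        taxa = [t for t in ("fish", "invertebrate", "algae") if rng.random() < 0.8]
        for t in taxa or ["fish"]:
            row[f"noec_{t}"] = f"{10.0 ** rng.normal(0.0, 1.0):.5g}"
    if rng.random() < cfg.p_acute_ec50:
        row["ec50_fish"] = f"{10.0 ** rng.normal(0.5, 1.0):.5g}"
    if rng.random() < cfg.p_qsar_votes:
        row["qsar_ec50s"] = ";".join(
            f"{10.0 ** rng.normal(0.5, 1.0):.5g}" for _ in range(4))
        row["qsar_t_votes"] = ";".join(
            "true" if rng.random() < 0.3 else "false" for _ in range(4))
    row["ed_flag"] = "true" if rng.random() < cfg.p_ed else "false"
    if rng.random() < cfg.p_use:
        tonnage = 10.0 ** rng.uniform(cfg.log10_tonnage_min, cfg.log10_tonnage_max)
        n_uses = int(rng.integers(1, 4))
        uses = sorted({USE_CATEGORIES[int(k)]
                       for k in rng.integers(0, len(USE_CATEGORIES), size=n_uses)})
        if rng.random() < 0.5:
            row["tonnage_iuclid"] = f"{tonnage:.4f}"
        else:
            v06, v07 = tonnage / 30.0, tonnage / 10.0
            row["spin_volumes"] = f"2006:{v06:.5f};2007:{v07:.5f}"
        row["use_entries"] = ";".join(uses)
    return row


def generate_substances(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate a synthetic substance table, deterministic under the seed.

    Planted archetypes occupy the first rows: known PBT positives
    first, then known benign negatives, then random substances.
    """
    cfg = config or GeneratorConfig()
    if cfg.n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(cfg.seed)
    n_pbt = int(round(cfg.pbt_fraction * cfg.n))
    n_benign = int(round(cfg.benign_fraction * cfg.n))
    rows = []
    for i in range(cfg.n):
        cas = synthesize_cas(i, int(rng.integers(10, 100)))
        if i < n_pbt:
            rows.append(_pbt_archetype_row(cas, i))
        elif i < n_pbt + n_benign:
            rows.append(_benign_archetype_row(cas, i))
        else:
            rows.append(_random_row(cas, i, cfg, rng))
    cols = list(SUBSTANCE_COLUMNS) + ["archetype"]
    return pd.DataFrame(rows, columns=cols).fillna("")


def generate_records(config: GeneratorConfig | None = None) -> list[SubstanceRecord]:
    """Generate records directly (same content as the table form)."""
    return records_from_dataframe(generate_substances(config))
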
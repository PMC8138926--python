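"""Reconstructed 145-case adult diffuse-glioma cohort.

The cohort table is the anchor of every downstream analysis: 45 IDH-mutant
1p/19q-codeleted oligodendrogliomas, 30 IDH-mutant astrocytomas, 16 IDH-wild-type
astrocytomas and 54 IDH-wild-type glioblastomas, with per-case immunostain calls
(H3K27me3 nuclear retention/loss, ATRX, p53), IDH mutation subtype, 1p/19q status,
sex and age. Published per-case data are not deposited, so the table is rebuilt
deterministically from the printed group counts and cross-tabulations; where the
joint distribution of markers inside a group is under-determined, the assignment
is a documented reconstruction (see docs/methods.md), not a published fact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

DIAGNOSIS_GROUPS = ("OLIGO_CODEL", "ASTRO_IDH_MUT", "ASTRO_IDH_WT", "GBM_IDH_WT")
IDH_SUBTYPES = (
    "IDH1_R132H",
    "IDH1_R132L",
    "IDH1_R132S",
    "IDH2_R172K",
    "IDH2_R172S",
    "IDH2_R172W",
    "WT",
)
COHORT_COLUMNS = [
    "case_id",
    "diagnosis_group",
    "idh",
    "atrx",
    "h3k27me3",
    "p53",
    "codeleted",
    "sex",
    "age",
]

# Printed age ranges per diagnosis group (years); for the two astrocytoma groups
# the union of the grade II / grade III rows is used.
AGE_RANGES = {
    "OLIGO_CODEL": (23, 72),
    "ASTRO_IDH_MUT": (25, 86),
    "ASTRO_IDH_WT": (31, 84),
    "GBM_IDH_WT": (28, 86),
}

# Male counts per group (printed); the remainder of each group is female.
_N_MALE = {"OLIGO_CODEL": 23, "ASTRO_IDH_MUT": 18, "ASTRO_IDH_WT": 8, "GBM_IDH_WT": 29}

_AGE_SEED = 20210521  # fixed, documented: ages are a seeded draw within ranges


@dataclass(frozen=True)
class CaseRecord:
    """One patient of the cohort."""

    case_id: str
    diagnosis_group: str
    idh: str
    atrx: str  # RETAINED | LOST
    h3k27me3: str  # NR (nuclear retention) | NL (nuclear loss)
    p53: str  # POS | NEG | NA
    codeleted: bool | None
    sex: str  # M | F
    age: int


def _oligo_rows() -> list[tuple[str, str, str, str]]:
    # (idh, h3k27me3, atrx, p53) for the 45 codeleted oligodendrogliomas.
    # 40 IDH1-R132H (36 NL / 4 NR; 39 ATRX retained / 1 lost), 5 non-canonical
    # (1 R132L, 2 R172K, 1 R172S, 1 R172W), all non-canonical NR.
    rows = []
    rows += [("IDH1_R132H", "NL", "RETAINED", "NEG")] * 35
    rows += [("IDH1_R132H", "NL", "LOST", "NEG")]
    rows += [("IDH1_R132H", "NR", "RETAINED", "NEG")] * 4
    rows += [("IDH1_R132L", "NR", "LOST", "NEG")]
    rows += [("IDH2_R172K", "NR", "RETAINED", "NEG")] * 2
    rows += [("IDH2_R172S", "NR", "RETAINED", "NEG")]
    rows += [("IDH2_R172W", "NR", "RETAINED", "NEG")]
    return rows


def _astro_mut_rows() -> list[tuple[str, str, str, str]]:
    # 30 IDH-mutant astrocytomas: 29 R132H + 1 R132S; 4 NL (all R132H);
    # 11 ATRX retained (all R132H). NL cases are co-assigned ATRX-lost.
    rows = []
    rows += [("IDH1_R132H", "NL", "LOST", "POS")] * 4
    rows += [("IDH1_R132H", "NR", "RETAINED", "POS")] * 11
    rows += [("IDH1_R132H", "NR", "LOST", "POS")] * 14
    rows += [("IDH1_R132S", "NR", "LOST", "POS")]
    return rows


def _idh_wt_rows(n: int, n_nl: int) -> list[tuple[str, str, str, str]]:
    rows = [("WT", "NL", "LOST", "NA")] * n_nl
    rows += [("WT", "NR", "RETAINED", "NA")] * (n - n_nl)
    return rows


def build_cohort_fixture() -> pd.DataFrame:
    """Build the deterministic 145-case cohort table.

    Returns a DataFrame with columns ``case_id, diagnosis_group, idh, atrx,
    h3k27me3, p53, codeleted, sex, age``. Repeated calls are bit-identical:
    marker assignments are a fixed enumeration and ages are drawn with a fixed
    seed uniformly within each group's printed range.
    """
    groups = [
        ("OLIGO_CODEL", "OD", _oligo_rows(), True),
        ("ASTRO_IDH_MUT", "AS", _astro_mut_rows(), False),
        ("ASTRO_IDH_WT", "AW", _idh_wt_rows(16, 1), False),
        ("GBM_IDH_WT", "GB", _idh_wt_rows(54, 5), False),
    ]
    rng = np.random.default_rng(_AGE_SEED)
    records = []
    for group, prefix, rows, codel in groups:
        lo, hi = AGE_RANGES[group]
        ages = rng.integers(lo, hi + 1, size=len(rows))
        n_male = _N_MALE[group]
        for i, ((idh, h3, atrx, p53), age) in enumerate(zip(rows, ages)):
            records.append(
                {
                    "case_id": f"{prefix}{i + 1:03d}",
                    "diagnosis_group": group,
                    "idh": idh,
                    "atrx": atrx,
                    "h3k27me3": h3,
                    "p53": p53,
                    "codeleted": codel,
                    "sex": "M" if i < n_male else "F",
                    "age": int(age),
                }
            )
    cohort = pd.DataFrame.from_records(records, columns=COHORT_COLUMNS)
    validate_cohort(cohort)
    return cohort


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check structural invariants of a cohort table; raise ValueError on breach."""
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if len(cohort) == 0:
        raise ValueError("cohort table is empty")
    bad_group = set(cohort["diagnosis_group"]) - set(DIAGNOSIS_GROUPS)
    if bad_group:
        raise ValueError(f"unknown diagnosis groups: {sorted(bad_group)}")
    bad_idh = set(cohort["idh"]) - set(IDH_SUBTYPES)
    if bad_idh:
        raise ValueError(f"unknown IDH subtypes: {sorted(bad_idh)}")
    oligo = cohort["diagnosis_group"] == "OLIGO_CODEL"
    codel = cohort["codeleted"].map(lambda v: bool(v) if pd.notna(v) else False)
    if not (codel == oligo).all():
        raise ValueError("codeleted must hold exactly for OLIGO_CODEL cases")
    wt = cohort["diagnosis_group"].isin(["ASTRO_IDH_WT", "GBM_IDH_WT"])
    if not ((cohort["idh"] == "WT") == wt).all():
        raise ValueError("idh = WT must hold exactly for the IDH-wild-type groups")
    for group, (lo, hi) in AGE_RANGES.items():
        ages = cohort.loc[cohort["diagnosis_group"] == group, "age"]
        if len(ages) and not ages.between(lo, hi).all():
            raise ValueError(f"ages out of printed range for {group}")


def add_idh1_r132h_column(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append the IDH1-R132H immunostain surrogate column (POS/NEG).

    Only the canonical R132H mutation is detected by the mutation-specific
    antibody; non-canonical IDH1/IDH2 mutants and wild-type cases stain negative.
    """
    out = cohort.copy()
    out["idh1_r132h"] = np.where(out["idh"] == "IDH1_R132H", "POS", "NEG")
    return out


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV (booleans as true/false, NA as empty field)."""
    out = cohort.copy()
    out["codeleted"] = out["codeleted"].map({True: "true", False: "false"})
    out["p53"] = out["p53"].replace({"NA": ""})
    out.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv` and validate it."""
    raw = pd.read_csv(path, dtype={"case_id": str}, keep_default_na=False)
    # pandas may have parsed true/false into bools already; normalize either way
    raw["codeleted"] = raw["codeleted"].map(
        lambda v: v if isinstance(v, (bool, np.bool_)) else str(v).strip().lower() == "true"
    )
    raw["p53"] = raw["p53"].replace({"": "NA"})
    raw["age"] = raw["age"].astype(int)
    validate_cohort(raw)
    return raw


def cohort_to_csv_text(cohort: pd.DataFrame) -> str:
    buf = io.StringIO()
    write_cohort_csv(cohort, buf)
    return buf.getvalue()
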
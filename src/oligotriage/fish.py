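"""FISH 1p/19q deletion calling from per-nucleus signal counts.

Dual-color probes pair a red target (1p36 or 19q13) with a green control on
the opposite arm (1q25 or 19p13). A nucleus showing one red and two green
signals carries the deleted pattern; two red and two green is disomic
(intact). An arm is called deleted when at least 50% of informative nuclei
show the deleted pattern, and 1p/19q codeletion requires both arms deleted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

PROBE_SETS = ("P1_1p36_1q25", "P19_19q13_19p13")
DELETION_FRACTION_THRESHOLD = 0.50  # inclusive: "50% of nuclei or more"


@dataclass(frozen=True)
class FISHDeletionCall:
    probe_set: str
    n_scored: int
    n_deleted_pattern: int
    fraction_deleted: float
    deleted: bool


def classify_nucleus_signals(n_red: int, n_green: int) -> str:
    """Classify one nucleus' signal pattern: DELETED / INTACT / UNINFORMATIVE.

    Only the canonical patterns enter the denominator: 1 red + 2 green is
    DELETED, 2 red + 2 green is INTACT. Anything else (truncation artifacts,
    polysomy, failed hybridization) is UNINFORMATIVE and excluded.
    """
    if n_red < 0 or n_green < 0:
        raise ValueError("signal counts must be non-negative")
    if n_red == 1 and n_green == 2:
        return "DELETED"
    if n_red == 2 and n_green == 2:
        return "INTACT"
    return "UNINFORMATIVE"


def call_deletion(table: pd.DataFrame) -> FISHDeletionCall:
    """Arm-level deletion call for one probe set's nucleus table.

    ``fraction_deleted`` = DELETED / (DELETED + INTACT); the arm is deleted
    when the fraction reaches 0.50 (inclusive). The table must contain a
    single probe set and at least one informative nucleus.
    """
    probe_sets = set(table["probe_set"].unique())
    if len(probe_sets) != 1:
        raise ValueError(f"expected one probe set per table, got {sorted(probe_sets)}")
    probe_set = probe_sets.pop()
    patterns = [
        classify_nucleus_signals(r, g)
        for r, g in zip(table["n_red"], table["n_green"])
    ]
    n_deleted = sum(p == "DELETED" for p in patterns)
    n_intact = sum(p == "INTACT" for p in patterns)
    n_informative = n_deleted + n_intact
    if n_informative == 0:
        raise ValueError("zero informative nuclei (no 1R2G or 2R2G pattern)")
    fraction = n_deleted / n_informative
    return FISHDeletionCall(
        probe_set=probe_set,
        n_scored=n_informative,
        n_deleted_pattern=n_deleted,
        fraction_deleted=fraction,
        deleted=fraction >= DELETION_FRACTION_THRESHOLD,
    )


def call_codeletion(call_1p: FISHDeletionCall, call_19q: FISHDeletionCall) -> bool:
    """Combined 1p/19q codeletion: true iff both arms are deleted."""
    if call_1p.probe_set == call_19q.probe_set:
        raise ValueError("codeletion requires calls from the two distinct probe sets")
    for call in (call_1p, call_19q):
        if call.probe_set not in PROBE_SETS:
            raise ValueError(f"unknown probe set: {call.probe_set!r}")
    return bool(call_1p.deleted and call_19q.deleted)


def read_fish_csv(path) -> pd.DataFrame:
    """Read a per-nucleus FISH table CSV (nucleus_id, probe_set, n_red, n_green)."""
    table = pd.read_csv(path)
    required = {"nucleus_id", "probe_set", "n_red", "n_green"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"FISH table missing columns: {sorted(missing)}")
    return table
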
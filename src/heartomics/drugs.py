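"""Late-stage drug annotation of prioritized targets.

A static table join: prioritized protein symbols are matched against a
drug/target/mechanism table restricted to phase III/IV clinical-trial
records.  The packaged fixture (``data/late_stage_cvd_drugs.tsv``) covers 15
late-stage cardiovascular drugs against ADRA1A, PPARG and ROCK2 with 5
mechanisms of action; users supply their own exports for other snapshots,
since live database snapshots drift and a file join is reproducible.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io import DrugTable, read_drug_table

logger = logging.getLogger("heartomics.drugs")

MIN_PHASE = 3


@dataclass
class TargetDrugMap:
    """Join result: per-target drug records plus distinct-count summaries."""

    records: pd.DataFrame  # columns: target, drug, mechanism, max_phase, indications
    targets: tuple[str, ...]

    def drugs_for(self, target: str) -> pd.DataFrame:
        return self.records[self.records["target"] == target]

    @property
    def summary(self) -> dict[str, int]:
        rec = self.records
        indications = {i for v in rec["indications"] for i in v}
        return {
            "n_targets_queried": len(self.targets),
            "n_targets_with_drugs": rec["target"].nunique(),
            "n_drugs": rec["drug"].nunique(),
            "n_mechanisms": rec["mechanism"].nunique(),
            "n_indications": len(indications),
        }


def packaged_drug_table() -> DrugTable:
    """The packaged late-stage cardiovascular drug-target fixture."""
    path = resources.files("heartomics.data").joinpath("late_stage_cvd_drugs.tsv")
    with resources.as_file(path) as p:
        return read_drug_table(p)


def annotate_targets(
    targets: Iterable[str], drugs: DrugTable, min_phase: int = MIN_PHASE
) -> TargetDrugMap:
    """Join target symbols against phase >= ``min_phase`` drug records.

    Targets without any matching record map to empty lists (logged at info
    level); an empty target set yields an empty map.  Output ordering is
    deterministic: (target, drug).
    """
    targets = tuple(sorted(set(targets)))
    df = drugs.data
    df = df[df["max_phase"] >= min_phase]
    joined = df[df["target"].isin(targets)].copy()
    joined = joined[["target", "drug", "mechanism", "max_phase", "indications"]]
    joined = joined.sort_values(["target", "drug"], kind="mergesort").reset_index(drop=True)
    hit = set(joined["target"])
    for t in targets:
        if t not in hit:
            logger.info("target %s has no phase >= %d drug record", t, min_phase)
    return TargetDrugMap(records=joined, targets=targets)


def sankey_table(mapping: TargetDrugMap) -> pd.DataFrame:
    """Three-column (indication, target, drug) table for Sankey-style plots."""
    rows = [
        {"indication": ind, "target": r.target, "drug": r.drug}
        for r in mapping.records.itertuples(index=False)
        for ind in r.indications
    ]
    df = pd.DataFrame(rows, columns=["indication", "target", "drug"])
    return df.sort_values(["indication", "target", "drug"], kind="mergesort").reset_index(drop=True)


def annotation_table(mapping: TargetDrugMap) -> pd.DataFrame:
    """Flat exportable annotation table (indications joined with ';')."""
    df = mapping.records.copy()
    df["indications"] = [";".join(v) for v in df["indications"]]
    return df
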
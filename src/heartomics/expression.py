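"""Cell-type z-score signatures and cross-dataset integration.

A gene's z-score in one cell type standardizes its mean log-normalized
expression against that gene's mean and population SD across all cell types
of one dataset.  Genes with z >= 2 and two-tailed p <= 0.001 are called
over-expressed in that cell type (z <= -2 for under-expression); the
significance call is the conjunction of both rules as printed, with the
p-rule binding at |z| >= 3.29.  Significant gene sets are intersected across
datasets to obtain the integrated signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionProfile

logger = logging.getLogger("heartomics.expression")

#: default significance thresholds
Z_HI = 2.0
Z_LO = -2.0
P_MAX = 0.001


@dataclass
class ZScoreTable:
    """Per (gene, cell_type) z-scores, two-tailed p-values and classes.

    ``data`` columns: gene, cell_type, mean_lognorm_expr, pct_expressing,
    z, p, class.  ``class`` is one of over / under / ns / undefined; genes
    constant across cell types (SD = 0) are ``undefined``.
    """

    dataset_id: str
    data: pd.DataFrame


@dataclass
class SignificantGeneSet:
    """Genes significant in a dataset (or in all datasets, ``"integrated"``).

    ``directions`` maps gene -> direction label: "over", "under", or "mixed"
    when calls disagree (between cell types or between datasets).
    """

    dataset_id: str
    directions: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.directions)


def compute_zscores(profile: ExpressionProfile, ddof: int = 0) -> ZScoreTable:
    """Standardize each gene across the cell types of one dataset.

    z = (x - mean) / SD with mean and SD taken across that gene's cell-type
    values; the SD is the population SD by default (``ddof=0``): the cell
    types of a dataset are the full population of profiles, and the
    two-cell-type case is then analytically clean (z = ±1).  Two-tailed p
    from the standard normal.  Constant genes get class ``undefined`` and a
    logged warning rather than an exception.
    """
    df = profile.data.copy()
    n_ct = df.groupby("gene")["cell_type"].transform("size")
    if (n_ct < 2).any():
        raise ValueError(
            f"dataset {profile.dataset_id}: every gene needs >=2 cell types"
        )
    grp = df.groupby("gene")["mean_lognorm_expr"]
    mean = grp.transform("mean")
    sd = grp.transform(lambda x: x.std(ddof=ddof))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (df["mean_lognorm_expr"] - mean) / sd
    df["z"] = z.where(sd > 0, np.nan)
    df["p"] = 2.0 * stats.norm.sf(np.abs(df["z"]))
    df["class"] = np.where(sd > 0, "ns", "undefined")
    n_const = int((sd == 0).sum() // n_ct[sd == 0].iloc[0]) if (sd == 0).any() else 0
    if n_const:
        logger.warning(
            "dataset %s: %d constant-expression gene(s) set to class=undefined",
            profile.dataset_id,
            n_const,
        )
    return classify_genes(ZScoreTable(dataset_id=profile.dataset_id, data=df))


def classify_genes(
    ztable: ZScoreTable,
    z_hi: float = Z_HI,
    z_lo: float = Z_LO,
    p_max: float = P_MAX,
) -> ZScoreTable:
    """(Re)assign over / under / ns classes at the given thresholds.

    over iff z >= z_hi AND p <= p_max; under iff z <= z_lo AND p <= p_max.
    ``undefined`` entries (constant genes) are never reclassified.
    """
    df = ztable.data.copy()
    defined = df["class"] != "undefined"
    over = defined & (df["z"] >= z_hi) & (df["p"] <= p_max)
    under = defined & (df["z"] <= z_lo) & (df["p"] <= p_max)
    df.loc[defined, "class"] = "ns"
    df.loc[over, "class"] = "over"
    df.loc[under, "class"] = "under"
    return ZScoreTable(dataset_id=ztable.dataset_id, data=df)


def significant_genes(ztable: ZScoreTable) -> SignificantGeneSet:
    """Gene-level significance: a gene is significant in a dataset when it is
    over- or under-expressed in at least one cell type."""
    sig = ztable.data[ztable.data["class"].isin(["over", "under"])]
    directions: dict[str, str] = {}
    for gene, sub in sig.groupby("gene"):
        dirs = set(sub["class"])
        directions[str(gene)] = dirs.pop() if len(dirs) == 1 else "mixed"
    return SignificantGeneSet(dataset_id=ztable.dataset_id, directions=directions)


def intersect_datasets(
    sets: list[SignificantGeneSet], require_consistent_direction: bool = True
) -> SignificantGeneSet:
    """Genes significant in ALL datasets (the integrated signature).

    With ``require_consistent_direction`` genes whose direction disagrees
    between datasets (or is mixed within one) are excluded and logged;
    otherwise they are retained with direction ``"mixed"``.
    """
    if not sets:
        raise ValueError("intersect_datasets needs at least one dataset")
    common = set(sets[0].directions)
    for s in sets[1:]:
        common &= set(s.directions)
    directions: dict[str, str] = {}
    dropped: list[str] = []
    for gene in sorted(common):
        dirs = {s.directions[gene] for s in sets}
        if len(dirs) == 1 and "mixed" not in dirs:
            directions[gene] = dirs.pop()
        elif require_consistent_direction:
            dropped.append(gene)
        else:
            directions[gene] = "mixed"
    if dropped:
        logger.warning(
            "integrated set: %d gene(s) excluded for inconsistent direction: %s",
            len(dropped),
            ", ".join(dropped[:10]),
        )
    return SignificantGeneSet(dataset_id="integrated", directions=directions)


def assign_cell_types(
    gene: str, ztables: list[ZScoreTable]
) -> list[tuple[str, float]]:
    """Rank the cell types of a significant gene by mean |z| across datasets.

    Returns (cell_type, mean |z|) pairs for every cell type where the gene is
    significant in at least one dataset, sorted by descending mean |z| with
    lexicographic tie-break; the first entry is the primary assignment.
    """
    rows = []
    for zt in ztables:
        sub = zt.data[zt.data["gene"] == gene]
        if not sub.empty:
            rows.append(sub)
    if not rows:
        raise KeyError(f"gene {gene} absent from all z-score tables")
    allz = pd.concat(rows)
    sig_cts = sorted(allz.loc[allz["class"].isin(["over", "under"]), "cell_type"].unique())
    if not sig_cts:
        raise KeyError(f"gene {gene} is not significant in any dataset")
    mean_absz = allz.groupby("cell_type")["z"].apply(lambda v: float(np.abs(v).mean()))
    ranked = sorted(
        ((ct, float(mean_absz[ct])) for ct in sig_cts),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked


def primary_cell_type_map(
    integrated: SignificantGeneSet, ztables: list[ZScoreTable]
) -> dict[str, str]:
    """Primary cell-type assignment for every gene of the integrated set."""
    return {g: assign_cell_types(g, ztables)[0][0] for g in sorted(integrated.genes)}


def summarize_cell_types(
    ztables: list[ZScoreTable],
    integrated: SignificantGeneSet,
    pct_min: float = 50.0,
) -> pd.DataFrame:
    """Per-dataset, per-cell-type summary of the integrated signature.

    ``mean_z`` averages z over significant entries of integrated genes whose
    percent-expressing exceeds ``pct_min`` (the filter applies only to this
    summary, never to significance calls).  ``n_significant`` counts
    significant entries; ``n_assigned`` counts integrated genes whose primary
    assignment is that cell type.  Cell types with zero qualifying entries get
    a row with count 0 and NaN mean.
    """
    assigned = primary_cell_type_map(integrated, ztables)
    n_assigned = pd.Series(assigned).value_counts()
    rows = []
    genes = integrated.genes
    for zt in ztables:
        df = zt.data[zt.data["gene"].isin(genes)]
        for ct in sorted(zt.data["cell_type"].unique()):
            sub = df[(df["cell_type"] == ct) & df["class"].isin(["over", "under"])]
            passing = sub[sub["pct_expressing"] > pct_min]
            rows.append(
                {
                    "dataset": zt.dataset_id,
                    "cell_type": ct,
                    "n_significant": len(sub),
                    "n_assigned": int(n_assigned.get(ct, 0)),
                    "mean_z": float(passing["z"].mean()) if len(passing) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def integrated_table(
    integrated: SignificantGeneSet, ztables: list[ZScoreTable]
) -> pd.DataFrame:
    """Integrated signature as a table: gene, direction, primary cell type and
    every significant cell type (comma-joined)."""
    rows = []
    for gene in sorted(integrated.genes):
        ranked = assign_cell_types(gene, ztables)
        rows.append(
            {
                "gene": gene,
                "direction": integrated.directions[gene],
                "primary_cell_type": ranked[0][0],
                "all_cell_types": ",".join(ct for ct, _ in ranked),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "direction", "primary_cell_type", "all_cell_types"])


def zscore_long_table(ztables: list[ZScoreTable]) -> pd.DataFrame:
    """Concatenate z-score tables into one exportable long table."""
    frames = []
    for zt in ztables:
        df = zt.data.copy()
        df.insert(0, "dataset", zt.dataset_id)
        frames.append(df[["dataset", "gene", "cell_type", "z", "p", "class"]])
    return pd.concat(frames, ignore_index=True)
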
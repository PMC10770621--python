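"""Readers and writers for every external table the pipeline touches.

All tabular formats are tab-separated UTF-8 with ``#`` comment lines skipped,
matching the export conventions of STRING- and SIGNOR-style resources.  Gene
and protein identifiers are treated as opaque, case-sensitive symbols; no
identifier mapping is performed.

Writers sort rows canonically and use a fixed float format, so
``write(read(x))`` is byte-stable.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger("heartomics.io")

_FLOAT_FMT = "%.10g"

#: Closed vocabulary of causal-edge effects (SIGNOR-style sign annotations).
EFFECT_SIGNS = {"up-regulates": +1, "down-regulates": -1}


class DataValidationError(ValueError):
    """An input file violates a structural invariant of its format."""


# ---------------------------------------------------------------------------
# in-memory types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionProfile:
    """One dataset's per-cell-type expression summary (a pseudo-profile).

    ``data`` columns: gene, cell_type, mean_lognorm_expr, pct_expressing,
    n_nuclei.  (gene, cell_type) pairs are unique; every gene carries the same
    cell-type label set.
    """

    dataset_id: str
    data: pd.DataFrame

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.data["cell_type"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())


@dataclass
class ConfidenceEdges:
    """Undirected protein-interaction edges with confidence on [0, 1]."""

    data: pd.DataFrame  # columns: protein_a, protein_b, confidence


@dataclass
class CausalEdges:
    """Directed signed causal edges with reliability r in (0, 1]."""

    data: pd.DataFrame  # columns: source, target, effect, reliability
    phenotype_nodes: list[str] = field(default_factory=list)


@dataclass
class AnnotationDatabase:
    """One annotation source (e.g. GO:BP): term id -> (description, gene set)."""

    source: str
    terms: dict[str, tuple[str, frozenset[str]]]

    @property
    def universe(self) -> frozenset[str]:
        """Union of all term gene sets — the annotated-gene universe."""
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return frozenset(out)


@dataclass
class DrugTable:
    """Drug -> target records with mechanism, max trial phase and indications."""

    data: pd.DataFrame  # columns: drug, target, mechanism, max_phase, indications


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", comment="#", encoding="utf-8", **kwargs)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing required column(s) {missing}")


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, encoding="utf-8")


# ---------------------------------------------------------------------------
# expression profiles
# ---------------------------------------------------------------------------

_EXPR_COLS = ["gene", "cell_type", "mean_lognorm_expr", "pct_expressing", "n_nuclei"]


def read_expression_profiles(path: str | Path, dataset_id: str) -> ExpressionProfile:
    """Read a per-cell-type expression summary TSV and validate it.

    Raises :class:`DataValidationError` on duplicate (gene, cell_type) rows,
    negative expression, or percent-expressing values outside [0, 100].
    """
    df = _read_tsv(path, dtype={"gene": str, "cell_type": str})
    _require_columns(df, _EXPR_COLS, path)
    df = df[_EXPR_COLS].copy()
    df["mean_lognorm_expr"] = df["mean_lognorm_expr"].astype(float)
    df["pct_expressing"] = df["pct_expressing"].astype(float)
    df["n_nuclei"] = df["n_nuclei"].astype(int)

    dup = df.duplicated(subset=["gene", "cell_type"])
    if dup.any():
        g, c = df.loc[dup.idxmax(), ["gene", "cell_type"]]
        raise DataValidationError(
            f"{path}: duplicate (gene, cell_type) row {g}/{c} in dataset {dataset_id}"
        )
    if (df["mean_lognorm_expr"] < 0).any():
        bad = df.loc[df["mean_lognorm_expr"] < 0, "gene"].iloc[0]
        raise DataValidationError(f"{path}: negative expression for gene {bad}")
    if ((df["pct_expressing"] < 0) | (df["pct_expressing"] > 100)).any():
        raise DataValidationError(f"{path}: pct_expressing outside [0, 100]")
    if (df["n_nuclei"] < 0).any():
        raise DataValidationError(f"{path}: negative nucleus count")

    # every gene must carry the identical cell-type label set
    cts_per_gene = df.groupby("gene")["cell_type"].apply(frozenset)
    if cts_per_gene.nunique() > 1:
        raise DataValidationError(
            f"{path}: cell-type label set differs between genes of dataset {dataset_id}"
        )
    return ExpressionProfile(dataset_id=dataset_id, data=df.reset_index(drop=True))


def write_expression_profiles(profile: ExpressionProfile, path: str | Path) -> None:
    df = profile.data.sort_values(["gene", "cell_type"], kind="mergesort")
    _write_tsv(df[_EXPR_COLS], path)


# ---------------------------------------------------------------------------
# confidence edges (STRING-like)
# ---------------------------------------------------------------------------


def read_confidence_edges(path: str | Path, scale: str = "auto") -> ConfidenceEdges:
    """Read a protein_a/protein_b/confidence TSV.

    ``scale`` is ``"unit"`` (scores already on [0, 1]), ``"milli"`` (STRING
    combined scores on [0, 1000], divided by 1000) or ``"auto"`` (milli when
    any score exceeds 1).  Scores outside both scales are a hard error.
    """
    df = _read_tsv(path, dtype={"protein_a": str, "protein_b": str})
    _require_columns(df, ["protein_a", "protein_b", "confidence"], path)
    df = df[["protein_a", "protein_b", "confidence"]].copy()
    df["confidence"] = df["confidence"].astype(float)
    if df[["protein_a", "protein_b"]].isna().any().any():
        raise DataValidationError(f"{path}: edge with missing endpoint")
    return ConfidenceEdges(data=normalize_confidence(df, scale=scale, context=str(path)))


def normalize_confidence(
    df: pd.DataFrame, scale: str = "auto", context: str = "confidence edges"
) -> pd.DataFrame:
    """Normalize the ``confidence`` column onto [0, 1].  Idempotent under auto."""
    if scale not in {"auto", "unit", "milli"}:
        raise ValueError(f"unknown confidence scale {scale!r}")
    conf = df["confidence"]
    if (conf < 0).any() or (conf > 1000).any():
        bad = conf[(conf < 0) | (conf > 1000)].iloc[0]
        raise DataValidationError(f"{context}: confidence {bad} outside both scales")
    if scale == "auto":
        scale = "milli" if (conf > 1).any() else "unit"
    out = df.copy()
    if scale == "milli":
        out["confidence"] = conf / 1000.0
    if (out["confidence"] > 1).any():
        bad = out.loc[out["confidence"] > 1, "confidence"].iloc[0]
        raise DataValidationError(f"{context}: confidence {bad} > 1 on declared unit scale")
    return out


def write_confidence_edges(edges: ConfidenceEdges, path: str | Path) -> None:
    df = edges.data.sort_values(["protein_a", "protein_b"], kind="mergesort")
    _write_tsv(df, path)


# ---------------------------------------------------------------------------
# causal edges (SIGNOR-like)
# ---------------------------------------------------------------------------


def read_causal_edges(
    path: str | Path, phenotype_nodes: list[str] | None = None
) -> CausalEdges:
    """Read a directed signed edge list with per-edge reliability.

    Phenotype nodes may be given explicitly or, by convention, flagged in an
    optional ``is_phenotype_target`` column (1 on rows whose target is a
    phenotype node).
    """
    df = _read_tsv(path, dtype={"source": str, "target": str, "effect": str})
    _require_columns(df, ["source", "target", "effect", "reliability"], path)
    df["reliability"] = df["reliability"].astype(float)

    unknown = sorted(set(df["effect"]) - set(EFFECT_SIGNS))
    if unknown:
        raise DataValidationError(
            f"{path}: unknown effect token(s) {unknown}; allowed: {sorted(EFFECT_SIGNS)}"
        )
    bad = (df["reliability"] <= 0) | (df["reliability"] > 1)
    if bad.any():
        raise DataValidationError(
            f"{path}: reliability {df.loc[bad, 'reliability'].iloc[0]} outside (0, 1]"
        )
    if phenotype_nodes is None:
        if "is_phenotype_target" in df.columns:
            flagged = df.loc[df["is_phenotype_target"].astype(int) == 1, "target"]
            phenotype_nodes = sorted(flagged.unique())
        else:
            phenotype_nodes = []
    cols = ["source", "target", "effect", "reliability"]
    if "is_phenotype_target" in df.columns:
        df = df.drop(columns=[c for c in df.columns if c not in cols])
    return CausalEdges(data=df[cols].copy(), phenotype_nodes=list(phenotype_nodes))


def write_causal_edges(edges: CausalEdges, path: str | Path) -> None:
    df = edges.data.sort_values(["source", "target", "effect"], kind="mergesort").copy()
    pheno = set(edges.phenotype_nodes)
    df["is_phenotype_target"] = df["target"].isin(pheno).astype(int)
    _write_tsv(df, path)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path, source: str | None = None) -> AnnotationDatabase:
    """Read a GMT file: each line is ``term<TAB>description<TAB>gene...``.

    The description field is retained (many GMT readers drop it).  Empty gene
    sets and duplicate term ids are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataValidationError(
                f"{path}:{lineno}: GMT line needs term, description and >=1 gene"
            )
        term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if not genes:
            raise DataValidationError(f"{path}:{lineno}: term {term} has an empty gene set")
        if term in terms:
            raise DataValidationError(f"{path}:{lineno}: duplicate term id {term}")
        terms[term] = (desc, frozenset(genes))
    return AnnotationDatabase(source=source or path.stem, terms=terms)


def write_gmt(db: AnnotationDatabase, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(db.terms):
            desc, genes = db.terms[term]
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# drug tables
# ---------------------------------------------------------------------------

_INDICATION_SEP = ";"


def read_drug_table(path: str | Path) -> DrugTable:
    """Read a drug/target/mechanism/max_phase/indications TSV.

    ``indications`` is a semicolon-separated list in one column.  Duplicate
    (drug, target) pairs are a hard error.
    """
    df = _read_tsv(path, dtype={"drug": str, "target": str, "mechanism": str})
    _require_columns(df, ["drug", "target", "mechanism", "max_phase", "indications"], path)
    df = df[["drug", "target", "mechanism", "max_phase", "indications"]].copy()
    df["max_phase"] = df["max_phase"].astype(int)
    dup = df.duplicated(subset=["drug", "target"])
    if dup.any():
        d, t = df.loc[dup.idxmax(), ["drug", "target"]]
        raise DataValidationError(f"{path}: duplicate drug-target pair {d}/{t}")
    df["indications"] = [
        tuple(s.strip() for s in str(v).split(_INDICATION_SEP) if s.strip())
        for v in df["indications"]
    ]
    return DrugTable(data=df)


def write_drug_table(table: DrugTable, path: str | Path) -> None:
    df = table.data.sort_values(["drug", "target"], kind="mergesort").copy()
    df["indications"] = [_INDICATION_SEP.join(v) for v in df["indications"]]
    _write_tsv(df, path)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_report(report: dict, outdir: str | Path) -> list[Path]:
    """Serialize a report bundle.

    ``report`` maps names to pandas DataFrames (written as TSV tables) or to
    JSON-serializable objects, which are merged into one machine-readable
    ``summary.json`` plus a human-readable ``summary.txt``.
    Returns the list of files written, sorted.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    scalars: dict = {}
    for name, obj in report.items():
        if isinstance(obj, pd.DataFrame):
            p = outdir / f"{name}.tsv"
            _write_tsv(obj, p)
            written.append(p)
        else:
            scalars[name] = obj
    if scalars:
        p = outdir / "summary.json"
        p.write_text(json.dumps(scalars, indent=2, sort_keys=True, default=str) + "\n")
        written.append(p)
        buf = _io.StringIO()
        for key in sorted(scalars):
            buf.write(f"== {key} ==\n")
            val = scalars[key]
            if isinstance(val, dict):
                for k in val:
                    buf.write(f"  {k}: {val[k]}\n")
            else:
                buf.write(f"  {val}\n")
        p = outdir / "summary.txt"
        p.write_text(buf.getvalue())
        written.append(p)
    return sorted(written)
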
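"""Tabular I/O for expression matrices, annotations, phenotypes and search results.

The interchange format is plain TSV throughout: an expression matrix is a
header row of sample ids followed by one numeric row per probeset; a
phenotype table has columns ``sample_id``, ``event``, ``time_years``,
``er_status``; scored-tuple reports are written with a fixed column set and a
deterministic row order so identical inputs always produce byte-identical
files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

MICROARRAY = "microarray"
RNASEQ = "rnaseq"
_PLATFORMS = (MICROARRAY, RNASEQ)

_ER_IN = {
    "pos": "positive",
    "positive": "positive",
    "neg": "negative",
    "negative": "negative",
    "unknown": "unknown",
    "na": "unknown",
    "": "unknown",
}
_ER_OUT = {"positive": "pos", "negative": "neg", "unknown": "unknown"}


@dataclass
class ExpressionMatrix:
    """Probesets × samples matrix of log2-scale expression.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by probeset id, columns by sample id, float64 log2
        expression.
    platform : str
        ``"microarray"`` or ``"rnaseq"``.
    annotation : dict
        Maps probeset id → gene symbol. A probeset with no symbol is simply
        absent from the map (never an empty string), so the "no gene symbol"
        filter rule is unambiguous.
    """

    values: pd.DataFrame
    platform: str = MICROARRAY
    annotation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.platform not in _PLATFORMS:
            raise ValidationError(f"unknown platform {self.platform!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicated probeset id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicated sample id {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_symbol(self, probeset_id: str):
        """Gene symbol for a probeset, or ``None`` if unannotated."""
        return self.annotation.get(probeset_id)

    def subset_probesets(self, probeset_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(probeset_ids)], self.platform, self.annotation
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)], self.platform, self.annotation
        )


@dataclass
class PhenotypeTable:
    """Per-sample outcome annotation.

    ``table`` is indexed by sample id with columns ``event_observed`` (bool),
    ``time_years`` (non-negative float) and ``er_status`` in
    {"positive", "negative", "unknown"}.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"event_observed", "time_years", "er_status"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"phenotype table missing columns {sorted(missing)}")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"duplicated sample id {dup!r}")
        t = self.table["time_years"].to_numpy(dtype=float)
        if np.any(~np.isfinite(t)) or np.any(t < 0):
            raise ValidationError("time_years must be finite and non-negative")
        bad = set(self.table["er_status"]) - {"positive", "negative", "unknown"}
        if bad:
            raise ValidationError(f"invalid er_status values {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# expression matrices


def _read_numeric_table(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.name is None or raw.shape[1] == 0:
        raise FormatError(f"{path}: malformed header (need id column + sample ids)")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{path}: duplicated row id {dup!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-numeric cell {raw.iat[r, c]!r} at row "
            f"{raw.index[r]!r}, column {raw.columns[c]!r}",
            row=raw.index[r],
            column=raw.columns[c],
        )
    return numeric.astype(float)


def read_expression_matrix(path, platform: str = MICROARRAY, annotation=None) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column probeset id, header of sample ids).

    ``annotation`` may be a dict or a path to a two-column TSV
    (probeset id, gene symbol).
    """
    values = _read_numeric_table(path)
    if annotation is not None and not isinstance(annotation, dict):
        annotation = read_annotation(annotation)
    return ExpressionMatrix(values, platform=platform, annotation=annotation or {})


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "id"
    df.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


def read_annotation(path) -> dict[str, str]:
    """Read a probeset → gene-symbol map; empty symbols mean "no annotation"."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: annotation needs two columns")
    out: dict[str, str] = {}
    for ps, sym in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if sym:
            out[ps] = sym
    return out


def write_annotation(annotation: dict[str, str], path) -> None:
    df = pd.DataFrame(sorted(annotation.items()), columns=["id", "gene_symbol"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_rpkm_table(path, pseudocount: float = 1.0, annotation=None) -> ExpressionMatrix:
    """Read gene-level RPKM values and return log2(RPKM + pseudocount) levels.

    RNA-seq expression enters the classifier on the same log2 scale as the
    microarray data; the pseudocount (default 1) keeps zero-read genes finite.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    values = _read_numeric_table(path)
    arr = values.to_numpy()
    if np.any(arr < 0):
        r, c = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"negative RPKM at row {values.index[r]!r}, column {values.columns[c]!r}"
        )
    if annotation is not None and not isinstance(annotation, dict):
        annotation = read_annotation(annotation)
    return ExpressionMatrix(
        np.log2(values + pseudocount), platform=RNASEQ, annotation=annotation or {}
    )


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotype_table(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "event", "time_years", "er_status"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    event = pd.to_numeric(df["event"], errors="coerce")
    if event.isna().any() or not set(event.astype(int)) <= {0, 1}:
        raise ParseError(f"{path}: event column must be 0/1")
    time = pd.to_numeric(df["time_years"], errors="coerce")
    if time.isna().any():
        raise ParseError(f"{path}: non-numeric time_years")
    er = df["er_status"].str.lower().map(_ER_IN)
    if er.isna().any():
        bad = df["er_status"][er.isna()].iloc[0]
        raise ValidationError(f"{path}: invalid er_status {bad!r}")
    table = pd.DataFrame(
        {
            "event_observed": event.astype(int).astype(bool).to_numpy(),
            "time_years": time.astype(float).to_numpy(),
            "er_status": er.to_numpy(),
        },
        index=pd.Index(df["sample_id"], name="sample_id"),
    )
    return PhenotypeTable(table)


def write_phenotype_table(pheno: PhenotypeTable, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": pheno.table.index,
            "event": pheno.table["event_observed"].astype(int).to_numpy(),
            "time_years": ["%.6f" % t for t in pheno.table["time_years"]],
            "er_status": [_ER_OUT[s] for s in pheno.table["er_status"]],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# scored-tuple reports


def _tuple_sort_key(st):
    return (-st.mean_auc_tf, st.probesets)


def scored_tuples_frame(tuples, annotation: dict[str, str] | None = None) -> pd.DataFrame:
    """Tabulate scored tuples (deterministic order: mean AUC desc, then tuple)."""
    annotation = annotation or {}
    rows = []
    roles: list[str] = []
    for st in tuples:
        for r in st.per_dataset:
            if r not in roles:
                roles.append(r)
    for st in sorted(tuples, key=_tuple_sort_key):
        row = {
            "probesets": ",".join(st.probesets),
            "genes": ",".join(annotation.get(p, "-") for p in st.probesets),
        }
        for role in roles:
            m = st.per_dataset.get(role)
            row[f"auc_{role}"] = m.auc if m else math.nan
            row[f"sens_{role}"] = m.sensitivity if m else math.nan
            row[f"spec_{role}"] = m.specificity if m else math.nan
        row["mean_auc_tf"] = st.mean_auc_tf
        row["C"] = st.classifier.C if st.classifier is not None else math.nan
        rows.append(row)
    cols = ["probesets", "genes"]
    for role in roles:
        cols += [f"auc_{role}", f"sens_{role}", f"spec_{role}"]
    cols += ["mean_auc_tf", "C"]
    return pd.DataFrame(rows, columns=cols)


def write_scored_tuples(tuples, path, annotation: dict[str, str] | None = None) -> None:
    """Write the scored-tuple report TSV (header always present, fixed formats)."""
    df = scored_tuples_frame(tuples, annotation)
    if df.empty:
        df = pd.DataFrame(
            columns=["probesets", "genes", "auc_training", "sens_training",
                     "spec_training", "mean_auc_tf", "C"]
        )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


def read_scored_tuples(path):
    """Read a scored-tuple report back into lightweight ScoredTuple records.

    Classifier coefficients are not serialized, so ``classifier`` is ``None``
    on the returned records; metric columns round-trip exactly at the written
    precision.
    """
    from .search import DatasetMetrics, ScoredTuple  # local import: no cycle at load

    df = pd.read_csv(path, sep="\t", dtype={"probesets": str, "genes": str})
    roles = [c[len("auc_"):] for c in df.columns if c.startswith("auc_")]
    out = []
    for _, row in df.iterrows():
        per = {}
        for role in roles:
            per[role] = DatasetMetrics(
                auc=float(row[f"auc_{role}"]),
                sensitivity=float(row[f"sens_{role}"]),
                specificity=float(row[f"spec_{role}"]),
            )
        out.append(
            ScoredTuple(
                probesets=tuple(str(row["probesets"]).split(",")),
                classifier=None,
                per_dataset=per,
                mean_auc_tf=float(row["mean_auc_tf"]),
            )
        )
    return out
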
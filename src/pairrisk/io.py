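"""Core data containers and tabular I/O.

Conventions follow the TCGA bulk-RNA-seq layout: expression matrices are
genes-in-rows, samples-in-columns, tab-delimited, on the FPKM scale. No
transform is ever applied at load time; log2(x+1) is taken explicitly by the
stage that needs it.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ModelIOError

logger = logging.getLogger("pairrisk")

MODEL_FORMAT_VERSION = 1

#: standard MAF variant-classification vocabulary
MAF_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Silent",
        "Intron",
        "IGR",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "RNA",
        "Splice_Region",
        "Targeted_Region",
    }
)


@dataclass
class ExpressionMatrix:
    """Nonnegative gene x sample expression values plus tissue labels.

    ``values`` is genes-in-rows; ``tissue`` maps every sample (column) to
    ``"tumor"`` or ``"normal"``.
    """

    values: pd.DataFrame
    tissue: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene IDs: {dupes[:5]}")
        if v.columns.duplicated().any():
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample IDs: {dupes[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataError("expression matrix contains non-numeric cells")
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise DataError(f"missing expression value at gene {v.index[r]!r}, sample {v.columns[c]!r}")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise DataError(f"negative expression value at gene {v.index[r]!r}, sample {v.columns[c]!r}")
        missing = set(v.columns) - set(self.tissue.index)
        if missing:
            raise DataError(f"samples without tissue label: {sorted(missing)[:5]}")
        bad = set(self.tissue.loc[list(v.columns)].unique()) - {"tumor", "normal"}
        if bad:
            raise DataError(f"unknown tissue labels: {sorted(bad)}")
        self.tissue = self.tissue.loc[list(v.columns)]

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def tumor_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.tissue[s] == "tumor"]

    def normal_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.tissue[s] == "normal"]


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001 - re-raise as a data error
        raise DataError(f"cannot parse {path}: {exc}") from exc


def read_expression(
    path,
    annotation_path=None,
    tissue_path=None,
    infer_tcga_tissue: bool = False,
    transpose: bool = False,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Load an expression matrix and its gene annotation.

    Parameters
    ----------
    path : tab-delimited matrix, genes in rows (set ``transpose=True`` for
        samples-in-rows files).
    annotation_path : optional TSV with columns ``gene``, ``symbol``,
        ``biotype``; genes absent from it are tagged ``biotype="other"``.
    tissue_path : optional two-column TSV ``sample<TAB>tissue``.
    infer_tcga_tissue : derive tumor/normal from the TCGA barcode sample-type
        field (01-09 tumor, 10-19 normal) when no tissue file is given.

    Returns ``(ExpressionMatrix, GeneAnnotation)`` where the annotation is a
    DataFrame indexed by gene ID with ``symbol`` and ``biotype`` columns.
    """
    values = _read_tsv(path)
    if transpose:
        values = values.T
    values.index = values.index.astype(str).str.strip()
    values.columns = values.columns.astype(str).str.strip()
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
            raise DataError(
                f"non-numeric cell in sample {col!r}"
                + (f" at gene {bad.index[0]!r}: {bad.iloc[0]!r}" if len(bad) else "")
            )

    if tissue_path is not None:
        tis = pd.read_csv(tissue_path, sep="\t", index_col=0).iloc[:, 0]
        tis.index = tis.index.astype(str).str.strip()
    elif infer_tcga_tissue:
        tis = pd.Series(
            ["tumor" if _tcga_sample_type(s) < 10 else "normal" for s in values.columns],
            index=values.columns,
        )
    else:
        raise DataError("tissue labels required: pass tissue_path or infer_tcga_tissue=True")

    if annotation_path is not None:
        annotation = read_annotation(annotation_path)
    else:
        annotation = pd.DataFrame(index=pd.Index([], name="gene"), columns=["symbol", "biotype"])
    missing = [g for g in values.index if g not in annotation.index]
    if missing:
        warnings.warn(
            f"{len(missing)} genes absent from annotation; tagged biotype='other'",
            stacklevel=2,
        )
        extra = pd.DataFrame({"symbol": missing, "biotype": "other"}, index=pd.Index(missing, name="gene"))
        annotation = pd.concat([annotation, extra])
    counts = annotation.loc[list(values.index), "biotype"].value_counts().to_dict()
    logger.info("loaded %d genes x %d samples; biotypes: %s", *values.shape, counts)
    return ExpressionMatrix(values=values, tissue=tis), annotation


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    required = {"gene", "symbol", "biotype"}
    if not required.issubset(ann.columns):
        raise DataError(f"annotation must have columns {sorted(required)}, got {list(ann.columns)}")
    ann["gene"] = ann["gene"].astype(str).str.strip()
    if ann["gene"].duplicated().any():
        raise DataError("duplicate gene IDs in annotation")
    return ann.set_index("gene")[["symbol", "biotype"]]


def _tcga_sample_type(sample: str) -> int:
    parts = sample.split("-")
    if len(parts) >= 4 and parts[3][:2].isdigit():
        return int(parts[3][:2])
    raise DataError(f"cannot infer tissue from sample ID {sample!r} (not a TCGA barcode)")


def truncate_tcga_barcodes(ids) -> list[str]:
    """TCGA patient-level IDs: first 12 characters of the barcode."""
    return [s[:12] for s in ids]


CLINICAL_REQUIRED = ("sample", "time", "event")
CLINICAL_COVARIATES = ("age", "sex", "grade", "stage")


def read_clinical(path) -> pd.DataFrame:
    """Load the clinical table, dropping invalid survival rows with a warning.

    Required columns: sample, time (days > 0), event (0 censored / 1 death).
    Optional covariates (age, sex, grade, stage) may contain missing values;
    rows with invalid time or event are excluded, mirroring the exclusion of
    incomplete follow-up records.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise DataError(f"clinical table missing required columns: {missing}")
    df["sample"] = df["sample"].astype(str).str.strip()
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    ok = (time > 0) & event.isin([0, 1])
    n_drop = int((~ok).sum())
    if n_drop:
        warnings.warn(f"{n_drop} dropped: invalid time or event", stacklevel=2)
    df = df.loc[ok].copy()
    df["time"] = time[ok].astype(float)
    df["event"] = event[ok].astype(int)
    if df["sample"].duplicated().any():
        raise DataError("duplicate sample IDs in clinical table")
    df = df.set_index("sample")
    if "sex" in df.columns:
        df["sex"] = df["sex"].astype("string").str.lower()
        bad_sex = ~df["sex"].isin(["male", "female"]) & df["sex"].notna()
        if bad_sex.any():
            df.loc[bad_sex, "sex"] = pd.NA
    return df


def read_maf(path) -> pd.DataFrame:
    """Load a MAF-format mutation table (tab-delimited, '#' comments)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"MAF missing required columns: {missing}")
    unknown = set(df["Variant_Classification"].unique()) - MAF_CLASSES
    if unknown:
        warnings.warn(
            f"MAF contains non-standard variant classes (kept, excluded from TMB): {sorted(unknown)}",
            stacklevel=2,
        )
    return df[required].copy()


def read_scores(path) -> pd.DataFrame:
    """Load a sample x feature score table (immune deconvolution output,
    checkpoint-gene expression, ...). Feature names must be unique."""
    df = _read_tsv(path)
    if df.columns.duplicated().any():
        raise DataError("duplicate feature names in score table")
    return df


# ---------------------------------------------------------------------------
# RiskModel serialization (self-describing key-value text format)
# ---------------------------------------------------------------------------


@dataclass
class RiskModel:
    """A fitted pair-signature Cox model.

    ``pairs`` are canonical (a, b) gene-ID tuples; ``coef`` the Cox log-hazard
    coefficients; ``cutoff`` the risk-score threshold separating high from low
    risk (``score > cutoff`` -> high). ``provenance`` records how selection
    was run (repeats, frequency threshold, seeds, per-pair frequencies).
    """

    pairs: list[tuple[str, str]]
    coef: np.ndarray
    cutoff: float | None = None
    auc_at_selection: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if len(self.pairs) != len(self.coef):
            raise DataError("pairs and coefficients differ in length")

    def score(self, pair_matrix: pd.DataFrame) -> pd.Series:
        """riskScore = sum_j coef_j * C_j over the model's pairs.

        ``pair_matrix`` is pairs-in-rows (index "A|B") x samples.
        """
        keys = [f"{a}|{b}" for a, b in self.pairs]
        missing = [k for k in keys if k not in pair_matrix.index]
        if missing:
            raise DataError(f"pair matrix missing model pairs: {missing}")
        sub = pair_matrix.loc[keys]
        return pd.Series(self.coef @ sub.to_numpy(), index=pair_matrix.columns, name="riskScore")

    def assign_groups(self, scores: pd.Series) -> pd.Series:
        if self.cutoff is None:
            raise DataError("model has no cutoff; run optimal_cutoff first")
        return pd.Series(
            np.where(scores.to_numpy() > self.cutoff, "high", "low"),
            index=scores.index,
            name="group",
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, RiskModel):
            return NotImplemented
        return (
            self.pairs == other.pairs
            and np.allclose(self.coef, other.coef, rtol=0, atol=1e-12)
            and _float_eq(self.cutoff, other.cutoff)
            and _float_eq(self.auc_at_selection, other.auc_at_selection)
            and self.provenance == other.provenance
        )


def _float_eq(a, b) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return abs(a - b) < 1e-12


def write_model(model: RiskModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pairrisk risk model\nformat_version: {MODEL_FORMAT_VERSION}\n")
        fh.write(f"n_pairs: {len(model.pairs)}\n")
        fh.write(f"cutoff: {_fmt(model.cutoff)}\n")
        fh.write(f"auc_at_selection: {_fmt(model.auc_at_selection)}\n")
        fh.write(f"provenance: {json.dumps(model.provenance, sort_keys=True)}\n")
        fh.write("pairs:\n")
        for (a, b), c in zip(model.pairs, model.coef):
            fh.write(f"{a}|{b}\t{float(c)!r}\n")


def _fmt(x) -> str:
    return "NA" if x is None else repr(float(x))


def _parse_opt(s: str) -> float | None:
    return None if s == "NA" else float(s)


def read_model(path) -> RiskModel:
    try:
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        head = {}
        i = 0
        while i < len(lines) and lines[i] != "pairs:":
            ln = lines[i]
            if ln and not ln.startswith("#"):
                key, _, val = ln.partition(": ")
                head[key] = val
            i += 1
        if i == len(lines):
            raise ModelIOError(f"{path}: no 'pairs:' section")
        version = int(head["format_version"])
        if version != MODEL_FORMAT_VERSION:
            raise ModelIOError(
                f"{path}: model format version {version} unsupported (expected {MODEL_FORMAT_VERSION})"
            )
        n_pairs = int(head["n_pairs"])
        pairs: list[tuple[str, str]] = []
        coef: list[float] = []
        for ln in lines[i + 1 :]:
            if not ln:
                continue
            pair_id, _, c = ln.partition("\t")
            a, _, b = pair_id.partition("|")
            if not b or not c:
                raise ModelIOError(f"{path}: malformed pair line {ln!r}")
            pairs.append((a, b))
            coef.append(float(c))
        if len(pairs) != n_pairs:
            raise ModelIOError(f"{path}: expected {n_pairs} pairs, found {len(pairs)}")
        return RiskModel(
            pairs=pairs,
            coef=np.asarray(coef),
            cutoff=_parse_opt(head["cutoff"]),
            auc_at_selection=_parse_opt(head["auc_at_selection"]),
            provenance=json.loads(head["provenance"]),
        )
    except ModelIOError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise ModelIOError(f"{path}: cannot parse model file: {exc}") from exc


def write_expression(expr: ExpressionMatrix, path, tissue_path=None) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")
    if tissue_path is not None:
        expr.tissue.rename("tissue").to_csv(tissue_path, sep="\t", index_label="sample")


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample")


def write_maf(maf: pd.DataFrame, path) -> None:
    maf.to_csv(path, sep="\t", index=False)
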
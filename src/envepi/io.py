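"""Tabular input/output for fold-change matrices, growth curves and results.

All tables are UTF-8, tab-delimited TSV with '.' decimal separators. A
fold-change matrix is features x samples of log2 fold changes relative to an
unstimulated baseline; each sample carries a binary (stimulusA, stimulusB)
design indicator. The baseline itself is the fold-change reference, not a
sample, so (0, 0) samples are rejected unless explicitly permitted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ParseError, SchemaError

CONDITION_LABELS = ("A", "B", "AB")

# header convention: <COND>_r<k> with COND in {A-name, B-name, A-name+B-name}
_SAMPLE_RE = re.compile(r"^(?P<cond>.+)_r(?P<rep>\d+)$")


def condition_label(a: int, b: int) -> str:
    """Map a (stimulusA, stimulusB) indicator pair to its condition label."""
    if (a, b) == (1, 0):
        return "A"
    if (a, b) == (0, 1):
        return "B"
    if (a, b) == (1, 1):
        return "AB"
    if (a, b) == (0, 0):
        return "BASELINE"
    raise SchemaError(f"invalid stimulus indicators ({a}, {b})")


@dataclass
class FoldChangeMatrix:
    """Log2 fold changes (features x samples) plus the 2x2 stimulus design.

    Parameters
    ----------
    values : DataFrame
        Rows are features (index = feature ids), columns are sample ids.
    samples : DataFrame
        Indexed by sample id, with integer columns ``stimulus_a``,
        ``stimulus_b`` and ``replicate``; row order matches the columns of
        ``values``.
    stimulus_names : tuple of str
        Display names of the two stimuli (default ``("HT", "G")``).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    stimulus_names: tuple[str, str] = ("HT", "G")
    n_dropped: int = 0
    allow_baseline: bool = False
    min_replicates: int = 2

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise SchemaError(f"duplicate feature ids: {list(dups)[:5]}")
        if list(self.values.columns) != list(self.samples.index):
            raise SchemaError("sample metadata does not match value columns")
        for col in ("stimulus_a", "stimulus_b", "replicate"):
            if col not in self.samples.columns:
                raise SchemaError(f"sample metadata missing column {col!r}")
        conds = self.condition_per_sample()
        if not self.allow_baseline and (conds == "BASELINE").any():
            bad = list(conds.index[conds == "BASELINE"])
            raise SchemaError(
                f"baseline (0,0) samples not permitted: {bad}; the baseline "
                "is the fold-change reference, not a sample"
            )
        counts = conds[conds != "BASELINE"].value_counts()
        for label in CONDITION_LABELS:
            if counts.get(label, 0) < self.min_replicates:
                raise SchemaError(
                    f"condition {label} has {counts.get(label, 0)} samples; "
                    f"each test condition needs >= {self.min_replicates}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def condition_per_sample(self) -> pd.Series:
        return pd.Series(
            [
                condition_label(int(a), int(b))
                for a, b in zip(self.samples["stimulus_a"], self.samples["stimulus_b"])
            ],
            index=self.samples.index,
            name="condition",
        )

    def condition_columns(self, label: str) -> list[str]:
        conds = self.condition_per_sample()
        return list(conds.index[conds == label])

    def swap_stimuli(self) -> "FoldChangeMatrix":
        """Return a copy with the A/B stimulus labels exchanged."""
        samples = self.samples.copy()
        samples[["stimulus_a", "stimulus_b"]] = samples[
            ["stimulus_b", "stimulus_a"]
        ].to_numpy()
        return FoldChangeMatrix(
            values=self.values.copy(),
            samples=samples,
            stimulus_names=(self.stimulus_names[1], self.stimulus_names[0]),
            n_dropped=self.n_dropped,
            allow_baseline=self.allow_baseline,
        )


@dataclass
class GrowthCurve:
    """An OD-vs-time growth curve (times in minutes, absorbance at 660 nm)."""

    times: np.ndarray
    od: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise SchemaError("times and od must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise SchemaError("times must be strictly increasing")
        if np.any(self.od <= 0):
            raise SchemaError("od values must be positive")


def _parse_sample_header(
    name: str, stimulus_names: tuple[str, str]
) -> tuple[int, int, int] | None:
    m = _SAMPLE_RE.match(name)
    if not m:
        return None
    cond, rep = m.group("cond"), int(m.group("rep"))
    a_name, b_name = stimulus_names
    mapping = {
        a_name: (1, 0),
        b_name: (0, 1),
        f"{a_name}{b_name}": (1, 1),
        f"{a_name}+{b_name}": (1, 1),
    }
    if cond not in mapping:
        return None
    a, b = mapping[cond]
    return a, b, rep


def read_fold_change_table(
    path: str | Path,
    schema: dict | None = None,
    *,
    require_complete: bool = True,
    stimulus_names: tuple[str, str] = ("HT", "G"),
) -> FoldChangeMatrix:
    """Read a TSV fold-change matrix.

    ``schema`` optionally maps column names to sample records, e.g.
    ``{"feature_id": "protein", "samples": {"c1": {"stimulus_a": 1,
    "stimulus_b": 0, "replicate": 1}, ...}}``. Without a schema, sample
    columns are parsed from the ``<COND>_r<k>`` header convention
    (``HT_r1``, ``G_r2``, ``HTG_r3``).

    With ``require_complete`` (the default) features missing a value in any
    sample are dropped; the count of dropped features is recorded on the
    returned matrix (``n_dropped``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if schema is not None:
        feat_col = schema.get("feature_id", df.columns[0])
        sample_map = schema.get("samples")
        if sample_map is None:
            raise SchemaError("schema must provide a 'samples' mapping")
        missing = [c for c in sample_map if c not in df.columns]
        if missing:
            raise SchemaError(f"schema columns absent from file: {missing}")
        records = {
            col: (int(rec["stimulus_a"]), int(rec["stimulus_b"]), int(rec["replicate"]))
            for col, rec in sample_map.items()
        }
        stimulus_names = tuple(schema.get("stimulus_names", stimulus_names))
    else:
        feat_col = df.columns[0]
        records = {}
        for col in df.columns[1:]:
            parsed = _parse_sample_header(col, stimulus_names)
            if parsed is not None:
                records[col] = parsed
        if not records:
            raise SchemaError(
                "no sample columns recognised; provide a schema or use "
                "<COND>_r<k> headers"
            )
    if feat_col not in df.columns:
        raise SchemaError(f"feature id column {feat_col!r} absent from file")

    sample_cols = list(records)
    values = df[[feat_col] + sample_cols].set_index(feat_col)
    values.index.name = "feature_id"
    numeric = pd.DataFrame(index=values.index)
    for col in sample_cols:
        raw = values[col].replace({"NA": np.nan, "": np.nan})
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & raw.notna()
        if bad.any():
            row = values.index[bad][0]
            raise ParseError(
                f"non-numeric value {values.loc[row, col]!r} at "
                f"feature {row!r}, column {col!r}"
            )
        numeric[col] = converted

    n_dropped = 0
    if require_complete:
        complete = numeric.dropna()
        n_dropped = len(numeric) - len(complete)
        numeric = complete

    samples = pd.DataFrame(
        {
            "stimulus_a": [records[c][0] for c in sample_cols],
            "stimulus_b": [records[c][1] for c in sample_cols],
            "replicate": [records[c][2] for c in sample_cols],
        },
        index=pd.Index(sample_cols, name="sample_id"),
    )
    return FoldChangeMatrix(
        values=numeric,
        samples=samples,
        stimulus_names=stimulus_names,
        n_dropped=n_dropped,
    )


def write_fold_change_table(matrix: FoldChangeMatrix, path: str | Path) -> None:
    """Write a fold-change matrix as TSV (header encodes condition/replicate)."""
    path = Path(path)
    a, b = matrix.stimulus_names
    label_map = {"A": a, "B": b, "AB": f"{a}{b}"}
    conds = matrix.condition_per_sample()
    header = {
        sid: f"{label_map[conds[sid]]}_r{int(matrix.samples.loc[sid, 'replicate'])}"
        for sid in matrix.samples.index
    }
    out = matrix.values.rename(columns=header)
    out.to_csv(path, sep="\t", float_format="%.10g")


def fold_changes_from_baseline(
    expression: pd.DataFrame,
    baseline_sample_ids: list[str],
    sample_design: pd.DataFrame,
    *,
    stimulus_names: tuple[str, str] = ("A", "B"),
) -> FoldChangeMatrix:
    """Convert a normalized expression table to baseline-referenced fold changes.

    Each test-sample entry becomes ``value - mean(baseline values)`` for that
    feature; baseline samples are excluded from the output. Unbalanced
    replicate counts across conditions are supported.

    Parameters
    ----------
    expression : DataFrame
        Features x samples of normalized expression (log scale assumed).
    baseline_sample_ids : list of str
        Columns of ``expression`` forming the baseline; must be non-empty and
        disjoint from the test samples described in ``sample_design``.
    sample_design : DataFrame
        Indexed by test sample id with columns ``stimulus_a``, ``stimulus_b``,
        ``replicate``.
    """
    if len(baseline_sample_ids) == 0:
        raise ConfigError("at least one baseline sample is required")
    missing = [s for s in baseline_sample_ids if s not in expression.columns]
    if missing:
        raise SchemaError(f"baseline samples absent from expression: {missing}")
    test_ids = list(sample_design.index)
    overlap = set(test_ids) & set(baseline_sample_ids)
    if overlap:
        raise ConfigError(f"baseline and test samples overlap: {sorted(overlap)}")
    missing = [s for s in test_ids if s not in expression.columns]
    if missing:
        raise SchemaError(f"test samples absent from expression: {missing}")
    baseline_mean = expression[baseline_sample_ids].mean(axis=1)
    fc = expression[test_ids].sub(baseline_mean, axis=0)
    return FoldChangeMatrix(
        values=fc, samples=sample_design.copy(), stimulus_names=stimulus_names
    )


def read_growth_curve(path: str | Path, condition_label: str = "") -> GrowthCurve:
    """Read a two-column (minutes, OD) TSV growth curve."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise SchemaError("growth curve TSV needs two columns (time, od)")
    return GrowthCurve(
        times=df.iloc[:, 0].to_numpy(float),
        od=df.iloc[:, 1].to_numpy(float),
        condition_label=condition_label or Path(path).stem,
    )


def write_growth_curve(curve: GrowthCurve, path: str | Path) -> None:
    pd.DataFrame({"minutes": curve.times, "od": curve.od}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write a bundle of result tables as deterministic TSVs.

    Keys become file names (``<key>.tsv``). Column and row order are taken as
    given by the caller, so reruns on identical inputs are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)
    return written
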
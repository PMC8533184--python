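"""Core containers and text I/O for methylation β-value analysis.

A :class:`BetaMatrix` holds per-probe, per-sample methylation fractions
(β values) in [0, 1]; a :class:`SampleSheet` carries the class label,
dataset of origin and optional tumour stage of every sample; a
:class:`Signature` is an ordered list of predictive CpG probes with their
Δβ (mean β in the positive class minus mean β in the reference class).

Files are plain text: β matrices are tab-separated with a ``probe_id``
header column, sample sheets are CSV, signatures are TSV with a JSON twin
for discovery metadata.  Missing β values are written as ``NA``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"
#: tokens accepted as "missing" when parsing a β matrix
MISSING_INPUT_TOKENS = frozenset({"NA", ""})

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "Signature",
    "read_beta_matrix",
    "write_beta_matrix",
    "intersect_probes",
    "drop_incomplete_probes",
    "read_sample_sheet",
    "align_labels",
    "MISSING_TOKEN",
]


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


class BetaMatrix:
    """Probe-by-sample matrix of methylation β values.

    β is the fraction of methylated signal at a CpG probe: 0 means fully
    unmethylated, 1 fully methylated.  Missing entries are NaN.  The
    container validates on construction: unique probe and sample ids,
    non-empty in both dimensions, and every non-missing value in [0, 1].

    Parameters
    ----------
    data : pandas.DataFrame
        Probes as the index, samples as the columns, float values.
    copy : bool
        Copy the frame (default) or adopt it as-is.
    """

    def __init__(self, data: pd.DataFrame, *, copy: bool = True):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("BetaMatrix expects a pandas DataFrame")
        df = data.copy() if copy else data
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError("degenerate matrix: needs >= 1 probe and >= 1 sample")
        _check_unique(list(df.index), "probe")
        _check_unique(list(df.columns), "sample")
        values = df.to_numpy(dtype=float)
        bad = (values < 0.0) | (values > 1.0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value out of [0,1] at probe {df.index[r]!r}, "
                f"sample {df.columns[c]!r}: {values[r, c]}"
            )
        self._data = pd.DataFrame(values, index=df.index, columns=df.columns)

    # -- accessors ---------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def probe_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def n_missing(self) -> int:
        return int(self._data.isna().to_numpy().sum())

    def is_complete(self) -> bool:
        return self.n_missing() == 0

    # -- subsetting --------------------------------------------------------
    def subset_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        missing = [p for p in probes if p not in self._data.index]
        if missing:
            raise KeyError(f"probes absent from matrix: {missing[:5]}")
        return BetaMatrix(self._data.loc[list(probes)], copy=True)

    def subset_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in samples if s not in self._data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return BetaMatrix(self._data[list(samples)], copy=True)

    def sample_vector(self, sample_id: str) -> pd.Series:
        return self._data[sample_id]

    # -- comparison --------------------------------------------------------
    def equals(self, other: "BetaMatrix") -> bool:
        return (
            self.probe_ids == other.probe_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p, s = self.shape
        return f"<BetaMatrix {p} probes x {s} samples, {self.n_missing()} missing>"


def read_beta_matrix(path: str | Path, *, sep: str = "\t") -> BetaMatrix:
    """Parse a delimited β-value file into a :class:`BetaMatrix`.

    First row: header cell (ignored) then sample ids.  First column: probe
    ids.  Cells must parse as decimals in [0, 1] (dot decimal separator)
    or be a missing token (``NA`` or empty).  Duplicate ids, out-of-range
    values and ragged rows are hard errors naming the offender.
    """
    path = Path(path)
    with path.open("r", newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        sample_ids = [h.strip() for h in header[1:]]
        if not sample_ids:
            raise ValueError(f"{path}: header contains no sample ids")
        _check_unique(sample_ids, "sample")
        n_cols = len(sample_ids)
        probe_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != n_cols + 1:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(row)} fields, "
                    f"expected {n_cols + 1})"
                )
            probe = row[0].strip()
            probe_ids.append(probe)
            vals = np.empty(n_cols, dtype=float)
            for j, tok in enumerate(row[1:]):
                tok = tok.strip()
                if tok in MISSING_INPUT_TOKENS:
                    vals[j] = np.nan
                    continue
                try:
                    v = float(tok)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: unparseable value {tok!r} at probe "
                        f"{probe!r}, sample {sample_ids[j]!r}"
                    ) from None
                if not 0.0 <= v <= 1.0:
                    raise ValueError(
                        f"{path}:{lineno}: value {v} out of [0,1] at probe "
                        f"{probe!r}, sample {sample_ids[j]!r}"
                    )
                vals[j] = v
            rows.append(vals)
        if not rows:
            raise ValueError(f"{path}: no probe rows")
        _check_unique(probe_ids, "probe")
    frame = pd.DataFrame(np.vstack(rows), index=probe_ids, columns=sample_ids)
    return BetaMatrix(frame, copy=False)


def write_beta_matrix(m: BetaMatrix, path: str | Path, *, sep: str = "\t") -> Path:
    """Serialize a β matrix as delimited text (missing values as ``NA``).

    Values are written with Python's shortest-round-trip float repr, so
    ``read_beta_matrix(write_beta_matrix(m))`` reproduces ``m`` exactly and
    two writes of the same matrix are byte-identical.
    """
    path = Path(path)
    m.data.to_csv(path, sep=sep, na_rep=MISSING_TOKEN, index_label="probe_id")
    return path


def intersect_probes(
    matrices: Sequence[BetaMatrix],
) -> tuple[BetaMatrix, list[str]]:
    """Merge matrices over their common probes, concatenating samples.

    Emulates pooling cohorts exported from different platforms, where a
    probe missing from any one export (e.g. the signature probe that could
    not be retrieved from an extension cohort) must be dropped everywhere.

    Returns the merged matrix (probe order follows the first input;
    sample columns concatenated in input order) and the list of dropped
    probe ids.  Raises on fewer than two inputs, duplicated sample ids
    across inputs, or an empty probe intersection.
    """
    if len(matrices) < 2:
        raise ValueError("intersect_probes needs >= 2 matrices")
    all_samples: list[str] = []
    for m in matrices:
        all_samples.extend(m.sample_ids)
    _check_unique(all_samples, "sample (across inputs)")
    common = set(matrices[0].probe_ids)
    union = set(matrices[0].probe_ids)
    for m in matrices[1:]:
        probes = set(m.probe_ids)
        common &= probes
        union |= probes
    if not common:
        raise ValueError("empty probe intersection across inputs")
    kept = [p for p in matrices[0].probe_ids if p in common]
    dropped = sorted(union - common)
    frames = [m.data.loc[kept] for m in matrices]
    merged = pd.concat(frames, axis=1)
    return BetaMatrix(merged, copy=False), dropped


def drop_incomplete_probes(m: BetaMatrix) -> tuple[BetaMatrix, list[str]]:
    """Restrict to probes with no missing values.

    Returns the restricted matrix and the ids of removed probes; errors
    when every probe has at least one missing value.  Idempotent.
    """
    complete = ~m.data.isna().any(axis=1)
    if not complete.any():
        raise ValueError("all probes have missing values")
    removed = [p for p, ok in zip(m.probe_ids, complete) if not ok]
    if not removed:
        return m, []
    return BetaMatrix(m.data.loc[complete], copy=False), removed


# ---------------------------------------------------------------------------
# sample sheet


class SampleSheet:
    """Per-sample metadata: class label, dataset id, optional tumour stage.

    ``stage`` (AJCC-style: I, IIA, IIB, IIIA, IIIC) may only be present on
    samples whose class is listed in ``tumour_classes``; pass ``None`` to
    skip that check when the label set is not known up front.
    """

    COLUMNS = ("sample_id", "class_label", "dataset_id", "stage")

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        tumour_classes: Iterable[str] | None = None,
    ):
        df = data.copy()
        for col in self.COLUMNS[:3]:
            if col not in df.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        if "stage" not in df.columns:
            df["stage"] = pd.NA
        df = df[list(self.COLUMNS)]
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(list(df["sample_id"]), "sample")
        stage_missing = df["stage"].isna() | (df["stage"].astype(str) == "")
        df.loc[stage_missing, "stage"] = pd.NA
        if tumour_classes is not None:
            tum = set(tumour_classes)
            staged = df.loc[~df["stage"].isna(), "class_label"]
            offenders = staged[~staged.isin(tum)]
            if len(offenders):
                raise ValueError(
                    "stage present on non-tumour sample(s): "
                    f"{list(df.loc[offenders.index, 'sample_id'])[:5]}"
                )
        self._data = df.reset_index(drop=True)

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data["sample_id"])

    @property
    def classes(self) -> list[str]:
        return sorted(self._data["class_label"].unique())

    def class_of(self) -> pd.Series:
        """Class label indexed by sample id."""
        return pd.Series(
            self._data["class_label"].to_numpy(),
            index=self._data["sample_id"].to_numpy(),
            name="class_label",
        )

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        idx = self._data["sample_id"].isin(set(sample_ids))
        return SampleSheet(self._data[idx])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self._data.copy()
        out["stage"] = out["stage"].astype(object).where(~out["stage"].isna(), "")
        out.to_csv(path, index=False)
        return path

    @classmethod
    def from_records(
        cls,
        records: Iterable[Sequence],
        *,
        tumour_classes: Iterable[str] | None = None,
    ) -> "SampleSheet":
        """Build from (sample_id, class_label, dataset_id[, stage]) tuples."""
        rows = [list(r) + [pd.NA] * (4 - len(r)) for r in records]
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(df, tumour_classes=tumour_classes)

    def __len__(self) -> int:
        return len(self._data)


def read_sample_sheet(
    path: str | Path, *, tumour_classes: Iterable[str] | None = None
) -> SampleSheet:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({"stage": {"": pd.NA}}) if "stage" in df.columns else df
    return SampleSheet(df, tumour_classes=tumour_classes)


def align_labels(m: BetaMatrix, sheet: SampleSheet) -> pd.Series:
    """Class labels ordered like the matrix columns.

    Any mismatch between the matrix's samples and the sheet's is a hard
    error: silent label/matrix misalignment is the most dangerous bug in
    this pipeline.
    """
    mat = set(m.sample_ids)
    sht = set(sheet.sample_ids)
    only_m = sorted(mat - sht)
    only_s = sorted(sht - mat)
    if only_m or only_s:
        raise ValueError(
            f"sample sheet / matrix mismatch: matrix-only={only_m[:5]}, "
            f"sheet-only={only_s[:5]}"
        )
    return sheet.class_of().loc[m.sample_ids]


# ---------------------------------------------------------------------------
# signature


@dataclass
class Signature:
    """Ordered list of predictive probes with per-probe Δβ.

    Δβ is the mean β in the positive (tumour) class minus the mean β in
    the reference class; negative values mean hypomethylation in the
    positive class.  ``metadata`` records how the signature was obtained
    (seed, fold scheme, chosen k and size).
    """

    probes: list[str]
    delta_beta: pd.Series
    genes: Mapping[str, str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.probes:
            raise ValueError("signature must contain at least one probe")
        _check_unique(self.probes, "signature probe")
        self.delta_beta = pd.Series(self.delta_beta, dtype=float).loc[self.probes]
        if (self.delta_beta.abs() > 1.0 + 1e-12).any():
            bad = self.delta_beta[self.delta_beta.abs() > 1.0 + 1e-12]
            raise ValueError(f"|delta_beta| > 1 for probe(s) {list(bad.index)[:5]}")

    def __len__(self) -> int:
        return len(self.probes)

    def gene_of(self, probe: str) -> str:
        return (self.genes or {}).get(probe, "")

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("probe_id\tdelta_beta\tgene\n")
            for p in self.probes:
                fh.write(f"{p}\t{float(self.delta_beta[p])!r}\t{self.gene_of(p)}\n")
        return path

    def to_json(self, path: str | Path) -> Path:
        """JSON twin carrying discovery metadata alongside the probe list."""
        path = Path(path)
        payload = {
            "probes": self.probes,
            "delta_beta": {p: self.delta_beta[p] for p in self.probes},
            "genes": dict(self.genes or {}),
            "metadata": self.metadata,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Signature":
        probes: list[str] = []
        dbeta: dict[str, float] = {}
        genes: dict[str, str] = {}
        with Path(path).open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["probe_id", "delta_beta"]:
                raise ValueError(f"{path}: not a signature TSV")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                probes.append(parts[0])
                dbeta[parts[0]] = float(parts[1])
                if len(parts) > 2 and parts[2]:
                    genes[parts[0]] = parts[2]
        return cls(probes, pd.Series(dbeta), genes=genes or None)
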
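"""Response-curve containers, stable-value feature extraction and CSV I/O.

A PEN3-style MOS e-nose records, for each sampled fruit, the conductivity
ratio G/G0 of ten metal-oxide sensors once per second over a 90 s collection
stage.  The curve rises quickly and plateaus; the plateau portion (the
"stable values", seconds 31-90 by default) is used directly as feature
rows - one row per retained second, no aggregation - so a single fruit
contributes 60 ten-dimensional feature vectors.

Two CSV schemas are supported:

* curve CSV (long): ``sample_id,class,time_s,sensor,ratio`` with
  ``sensor`` in MOS1..MOS10 and ``time_s`` in 1..duration;
* feature CSV (wide): ``sample_id,class,MOS1,...,MOS10``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CurveParseError, DataValidationError, SchemaError, WindowError

SENSORS: tuple[str, ...] = tuple(f"MOS{i}" for i in range(1, 11))
N_SENSORS = len(SENSORS)
N_CLASSES = 6
DEFAULT_DURATION = 90
#: inclusive stable-value window in seconds (1-based)
SV_WINDOW = (31, 90)

_CURVE_COLUMNS = ["sample_id", "class", "time_s", "sensor", "ratio"]
_FEATURE_COLUMNS = ["sample_id", "class", *SENSORS]
# 12 significant digits survive a float round-trip for these O(1) ratios
_FLOAT_FMT = "%.12g"


@dataclass
class ResponseCurve:
    """One sample's 10-sensor conductivity-ratio trace.

    Parameters
    ----------
    sample_id : str
        Opaque identifier of the fruit.
    class_label : int
        Browning grade in 0..5 (0 = healthy core).
    ratios : ndarray of shape (duration, 10)
        G/G0 ratios at 1 Hz, time-major, sensor columns ordered MOS1..MOS10.

    Shape and label range are checked at construction; value validity
    (finite, strictly positive ratios) is checked by :meth:`validate`, which
    feature extraction calls so that bad values are reported with the
    sample id they belong to.
    """

    sample_id: str
    class_label: int
    ratios: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.ndim != 2 or self.ratios.shape[1] != N_SENSORS:
            raise SchemaError(
                f"sample {self.sample_id!r}: ratios must be (duration, "
                f"{N_SENSORS}), got {self.ratios.shape}"
            )
        if not (isinstance(self.class_label, (int, np.integer))
                and 0 <= int(self.class_label) < N_CLASSES):
            raise DataValidationError(
                f"sample {self.sample_id!r}: class label {self.class_label!r} "
                f"outside 0..{N_CLASSES - 1}"
            )
        self.class_label = int(self.class_label)

    @property
    def duration(self) -> int:
        """Number of recorded seconds."""
        return self.ratios.shape[0]

    def validate(self) -> None:
        """Raise :class:`DataValidationError` unless all ratios are finite
        and strictly positive."""
        if not np.all(np.isfinite(self.ratios)):
            raise DataValidationError(
                f"sample {self.sample_id!r}: non-finite G/G0 ratio"
            )
        if np.any(self.ratios <= 0):
            raise DataValidationError(
                f"sample {self.sample_id!r}: non-positive G/G0 ratio"
            )


@dataclass
class FeatureTable:
    """Aligned stable-value matrix, labels and sample ids.

    ``X`` is N x 10 (one row per retained second), ``y`` the length-N grade
    vector, ``ids`` the length-N sample-id vector (each id repeated once per
    retained second when the table is built from full curves).
    """

    X: np.ndarray
    y: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.X.ndim != 2:
            raise SchemaError("X must be 2-D")
        if not (len(self.X) == len(self.y) == len(self.ids)):
            raise SchemaError(
                f"misaligned table: {len(self.X)} feature rows, "
                f"{len(self.y)} labels, {len(self.ids)} ids"
            )
        if len(self.y) and (self.y.min() < 0 or self.y.max() >= N_CLASSES):
            raise DataValidationError("labels outside 0..5")
        if not np.all(np.isfinite(self.X)):
            raise DataValidationError("feature table contains non-finite values")

    def __len__(self) -> int:
        return len(self.y)

    def class_counts(self) -> np.ndarray:
        """Row count per grade 0..5."""
        return np.bincount(self.y, minlength=N_CLASSES)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(SENSORS))
        df.insert(0, "class", self.y)
        df.insert(0, "sample_id", self.ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        missing = [c for c in _FEATURE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"feature frame missing columns {missing}")
        return cls(
            X=df[list(SENSORS)].to_numpy(dtype=float),
            y=df["class"].to_numpy(dtype=int),
            ids=df["sample_id"].to_numpy(dtype=object),
        )


def extract_stable_values(
    curve: ResponseCurve,
    window_start: int = SV_WINDOW[0],
    window_end: int = SV_WINDOW[1],
) -> np.ndarray:
    """Slice the plateau seconds out of a curve, one feature row per second.

    The window is 1-based and inclusive on both ends, so the default 31-90
    window of a 90 s curve yields a 60 x 10 block copied verbatim from the
    trace.

    Returns
    -------
    ndarray of shape (window_end - window_start + 1, 10)
    """
    if not (1 <= window_start <= window_end <= curve.duration):
        raise WindowError(
            f"window [{window_start}, {window_end}] outside curve duration "
            f"1..{curve.duration} (sample {curve.sample_id!r})"
        )
    curve.validate()
    return curve.ratios[window_start - 1:window_end].copy()


def assemble_feature_table(
    curves: list[ResponseCurve],
    window_start: int = SV_WINDOW[0],
    window_end: int = SV_WINDOW[1],
    standardize: bool = False,
) -> FeatureTable:
    """Stack stable-value blocks of many curves into one labelled table.

    Rows are ordered by input curve, then time, so the layout is
    deterministic.  With the default window, 240 curves give the
    14,400 x 10 training layout and 102 curves the 6,120 x 10 test layout.

    ``standardize=True`` z-scores each sensor column (off by default: raw
    stable values are used as-is).
    """
    if not curves:
        raise SchemaError("cannot assemble a table from zero curves")
    for c in curves:
        if c.ratios.shape[1] != N_SENSORS:  # defensive; ResponseCurve enforces
            raise SchemaError(f"sample {c.sample_id!r}: inconsistent sensor count")
    blocks, labels, ids = [], [], []
    for c in curves:
        block = extract_stable_values(c, window_start, window_end)
        blocks.append(block)
        labels.extend([c.class_label] * len(block))
        ids.extend([c.sample_id] * len(block))
    X = np.vstack(blocks)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return FeatureTable(X=X, y=np.asarray(labels), ids=np.asarray(ids, dtype=object))


# ---------------------------------------------------------------------------
# CSV I/O


def write_curves_csv(curves: list[ResponseCurve], path) -> None:
    """Write curves in the long schema, one row per (sample, second, sensor)."""
    frames = []
    for c in curves:
        c.validate()
        t = np.arange(1, c.duration + 1)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(c.sample_id, c.duration * N_SENSORS),
                    "class": c.class_label,
                    "time_s": np.repeat(t, N_SENSORS),
                    "sensor": np.tile(SENSORS, c.duration),
                    "ratio": c.ratios.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_curves_csv(path) -> list[ResponseCurve]:
    """Parse a long-format curve CSV back into curves.

    Validation errors (unknown sensor/class, duplicate keys, missing
    seconds) raise :class:`CurveParseError` with 1-based file line numbers
    (header = line 1).
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CurveParseError(f"{path}: {exc}") from exc
    if list(df.columns) != _CURVE_COLUMNS:
        raise CurveParseError(
            f"{path}: expected header {','.join(_CURVE_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    lines = df.index + 2  # data starts on file line 2

    bad_sensor = ~df["sensor"].isin(SENSORS)
    if bad_sensor.any():
        where = lines[bad_sensor][:5].tolist()
        raise CurveParseError(f"{path}: unknown sensor name at line(s) {where}")
    cls = pd.to_numeric(df["class"], errors="coerce")
    bad_cls = cls.isna() | (cls < 0) | (cls >= N_CLASSES) | (cls != cls.round())
    if bad_cls.any():
        where = lines[bad_cls][:5].tolist()
        raise CurveParseError(f"{path}: unknown class label at line(s) {where}")
    dup = df.duplicated(subset=["sample_id", "time_s", "sensor"], keep=False)
    if dup.any():
        where = lines[dup][:5].tolist()
        raise CurveParseError(
            f"{path}: duplicate (sample_id, time_s, sensor) rows at line(s) {where}"
        )

    duration = int(df["time_s"].max())
    curves: list[ResponseCurve] = []
    # preserve first-appearance order of samples
    for sid in df["sample_id"].drop_duplicates():
        sub = df[df["sample_id"] == sid]
        labels = sub["class"].unique()
        if len(labels) != 1:
            raise CurveParseError(
                f"{path}: sample {sid!r} carries conflicting class labels {sorted(labels)}"
            )
        for sensor in SENSORS:
            n = int((sub["sensor"] == sensor).sum())
            if n != duration:
                raise CurveParseError(
                    f"{path}: sample {sid!r} sensor {sensor} has {n} of "
                    f"{duration} time steps"
                )
        wide = sub.pivot(index="time_s", columns="sensor", values="ratio")
        wide = wide.reindex(index=np.arange(1, duration + 1), columns=list(SENSORS))
        if wide.isna().any().any():
            raise CurveParseError(
                f"{path}: sample {sid!r} is missing (time_s, sensor) rows"
            )
        curves.append(
            ResponseCurve(
                sample_id=str(sid),
                class_label=int(labels[0]),
                ratios=wide.to_numpy(dtype=float),
            )
        )
    return curves


def write_feature_csv(table: FeatureTable, path) -> None:
    """Write a feature table in the wide schema."""
    table.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_csv(path) -> FeatureTable:
    """Read a wide feature CSV; malformed content raises CurveParseError."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CurveParseError(f"{path}: {exc}") from exc
    if list(df.columns) != _FEATURE_COLUMNS:
        raise CurveParseError(
            f"{path}: expected header {','.join(_FEATURE_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    if df[list(SENSORS)].isna().any().any():
        bad = df.index[df[list(SENSORS)].isna().any(axis=1)] + 2
        raise CurveParseError(f"{path}: missing values at line(s) {bad[:5].tolist()}")
    try:
        return FeatureTable.from_frame(df)
    except (SchemaError, DataValidationError) as exc:
        raise CurveParseError(f"{path}: {exc}") from exc
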
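"""Tabular cohort handling: records, schema, vocabulary and encoding.

A patient is a *set* of (feature-name, value) pairs plus a right-censored
survival outcome. Missing measurements are simply absent from the set —
they are never encoded as sentinel values. Records are tokenized into
fixed-length rows headed by a special TASK token, with absent slots
padded; the maximum row length is chosen from the empirical distribution
of per-patient feature counts.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord", "Cohort", "Schema", "Vocabulary", "EncodedBatch",
    "read_cohort", "write_cohort", "encode_categoricals",
    "compute_max_length", "sample_and_pad", "encode_cohort",
]

#: strings treated as missing in delimited files
NA_STRINGS = ("", "NA", "NaN", "nan")

PAD_TOKEN = "[PAD]"
TASK_TOKEN = "[TASK]"
MASK_TOKEN = "[MASK]"


@dataclass
class PatientRecord:
    """One patient: non-missing features and a right-censored outcome."""

    patient_id: str
    features: dict[str, float]  # name -> value, non-missing only
    time: float
    event: int

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.patient_id}")
        if self.event not in (0, 1):
            raise ValueError(
                f"event indicator must be 0 or 1, got {self.event!r} "
                f"for {self.patient_id}")

    @property
    def n_features(self) -> int:
        return len(self.features)


class Cohort:
    """An ordered collection of :class:`PatientRecord`."""

    def __init__(self, records: list[PatientRecord]):
        ids = [r.patient_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids in cohort")
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        if isinstance(i, (list, np.ndarray)):
            return Cohort([self.records[j] for j in i])
        return self.records[i]

    @property
    def feature_names(self) -> list[str]:
        """Unique feature names in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            for name in r.features:
                seen.setdefault(name, None)
        return list(seen)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records], dtype=float)

    @property
    def events(self) -> np.ndarray:
        return np.array([r.event for r in self.records], dtype=int)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def feature_values(self, name: str, patient_ids=None) -> np.ndarray:
        """Observed values of one feature (missing entries excluded)."""
        keep = None if patient_ids is None else set(patient_ids)
        return np.array([r.features[name] for r in self.records
                         if name in r.features
                         and (keep is None or r.patient_id in keep)],
                        dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        """Wide table with NaN for missing entries (column order stable)."""
        rows = []
        for r in self.records:
            row = {"patient_id": r.patient_id, "time": r.time, "event": r.event}
            row.update(r.features)
            rows.append(row)
        df = pd.DataFrame(rows)
        cols = ["patient_id", "time", "event"] + [
            c for c in self.feature_names if c in df.columns]
        return df[cols]


@dataclass
class Schema:
    """Column roles and declared feature types for a cohort file.

    ``feature_types`` maps feature name -> 'continuous' | 'binary' |
    'categorical'. Categorical codebooks and continuous standardization
    statistics are fitted on training data and stored here so the same
    transform is replayed at inference.
    """

    id_col: str = "patient_id"
    time_col: str = "time"
    event_col: str = "event"
    feature_types: dict[str, str] = field(default_factory=dict)
    codebooks: dict[str, dict[str, int]] = field(default_factory=dict)
    standardize: bool = False
    scale_stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    UNSEEN = -1  # ordinal reserved for categories unseen at fit time

    @property
    def feature_cols(self) -> list[str]:
        return list(self.feature_types)

    def to_json(self) -> str:
        return json.dumps({
            "id_col": self.id_col, "time_col": self.time_col,
            "event_col": self.event_col, "feature_types": self.feature_types,
            "codebooks": self.codebooks, "standardize": self.standardize,
            "scale_stats": {k: list(v) for k, v in self.scale_stats.items()},
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Schema":
        d = json.loads(text)
        d["scale_stats"] = {k: tuple(v) for k, v in d.get("scale_stats", {}).items()}
        return cls(**d)

    # -- fitting ---------------------------------------------------------
    def fit_codebooks(self, df: pd.DataFrame) -> None:
        """Assign ordinals 0..n-1 per categorical column, sorted by label."""
        for col, kind in self.feature_types.items():
            if kind != "categorical" or col in self.codebooks \
                    or col not in df.columns:
                continue
            levels = sorted(df[col].dropna().astype(str).unique())
            self.codebooks[col] = {lab: i for i, lab in enumerate(levels)}

    def fit_scaling(self, cohort: "Cohort") -> None:
        """Store mean/sd of each continuous feature from training data."""
        for col, kind in self.feature_types.items():
            if kind != "continuous":
                continue
            vals = cohort.feature_values(col)
            if len(vals) == 0:
                continue
            sd = float(vals.std())
            self.scale_stats[col] = (float(vals.mean()), sd if sd > 0 else 1.0)

    def apply_scaling(self, cohort: "Cohort") -> "Cohort":
        if not self.standardize or not self.scale_stats:
            return cohort
        out = []
        for r in cohort:
            feats = dict(r.features)
            for col, (mu, sd) in self.scale_stats.items():
                if col in feats:
                    feats[col] = (feats[col] - mu) / sd
            out.append(PatientRecord(r.patient_id, feats, r.time, r.event))
        return Cohort(out)


class Vocabulary:
    """Feature-name token ids with reserved PAD/TASK/MASK slots.

    PAD=0, TASK=1, MASK=2; feature ids follow in insertion order. The
    vocabulary is serialized with checkpoints so that fine-tuning reuses
    pretraining ids.
    """

    N_RESERVED = 3
    PAD, TASK, MASK = 0, 1, 2

    def __init__(self, feature_names: list[str] | None = None):
        self._name_to_id: dict[str, int] = {
            PAD_TOKEN: self.PAD, TASK_TOKEN: self.TASK, MASK_TOKEN: self.MASK}
        for name in (feature_names or []):
            self.add(name)

    def add(self, name: str) -> int:
        if name not in self._name_to_id:
            self._name_to_id[name] = len(self._name_to_id)
        return self._name_to_id[name]

    def id_of(self, name: str) -> int:
        return self._name_to_id[name]

    def name_of(self, token_id: int) -> str:
        return self.id_to_name[token_id]

    @property
    def id_to_name(self) -> list[str]:
        return list(self._name_to_id)

    @property
    def feature_names(self) -> list[str]:
        return self.id_to_name[self.N_RESERVED:]

    def __len__(self) -> int:
        return len(self._name_to_id)

    def __contains__(self, name: str) -> bool:
        return name in self._name_to_id

    @property
    def n_features(self) -> int:
        return len(self) - self.N_RESERVED

    def to_json(self) -> str:
        return json.dumps({"features": self.feature_names})

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        return cls(json.loads(text)["features"])

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "Vocabulary":
        return cls(sorted(cohort.feature_names))


@dataclass
class EncodedBatch:
    """Tokenized, padded rows ready for the encoder.

    Row layout: position 0 is always ``[TASK, 1]``; feature slots follow;
    remaining slots are PAD (mask True). ``pad_mask`` marks positions to
    exclude from attention and losses.
    """

    token_ids: np.ndarray  # (batch, L) int
    values: np.ndarray     # (batch, L) float
    pad_mask: np.ndarray   # (batch, L) bool, True where PAD

    def __post_init__(self):
        assert self.token_ids.shape == self.values.shape == self.pad_mask.shape

    @property
    def L(self) -> int:
        return self.token_ids.shape[1]

    def __len__(self) -> int:
        return self.token_ids.shape[0]


# ----------------------------------------------------------------------
# file I/O

def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_cohort(path, schema: Schema, fit: bool = False) -> Cohort:
    """Read a delimited cohort file into a :class:`Cohort`.

    Empty cells and ``NA`` become absent features. With ``fit=True`` the
    schema's categorical codebooks (and scaling statistics if
    ``schema.standardize``) are fitted from this file; otherwise existing
    codebooks are reused and unseen categories map to a reserved ordinal
    with a warning.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     na_values=list(NA_STRINGS), encoding="utf-8")
    return cohort_from_dataframe(df, schema, fit=fit)


def cohort_from_dataframe(df: pd.DataFrame, schema: Schema,
                          fit: bool = False) -> Cohort:
    for col in (schema.time_col, schema.event_col):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from cohort file")
    if fit:
        schema.fit_codebooks(df)
    df = encode_categoricals_df(df, schema)
    records = []
    for i, row in df.iterrows():
        pid = str(row[schema.id_col]) if schema.id_col in df.columns else str(i)
        time = float(row[schema.time_col])
        event_raw = float(row[schema.event_col])
        if event_raw not in (0.0, 1.0):
            raise ValueError(f"event indicator must be 0 or 1, got {event_raw}")
        feats = {}
        for col in schema.feature_cols:
            if col not in df.columns:
                continue
            val = row[col]
            if pd.isna(val):
                continue
            feats[col] = float(val)
        records.append(PatientRecord(pid, feats, time, int(event_raw)))
    cohort = Cohort(records)
    if schema.standardize:
        if fit:
            schema.fit_scaling(cohort)
        cohort = schema.apply_scaling(cohort)
    return cohort


def write_cohort(cohort: Cohort, path, sep: str = ",") -> None:
    """Write a cohort as delimited text (missing entries left empty)."""
    df = cohort.to_dataframe()
    buf = io.StringIO()
    df.to_csv(buf, sep=sep, index=False, na_rep="")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def encode_categoricals_df(df: pd.DataFrame, schema: Schema) -> pd.DataFrame:
    """Replace categorical labels by their fitted ordinal codes."""
    import warnings

    df = df.copy()
    for col, kind in schema.feature_types.items():
        if kind != "categorical" or col not in df.columns:
            continue
        if col not in schema.codebooks:
            raise ValueError(f"categorical feature {col!r} has no codebook; "
                             "fit the schema on training data first")
        book = schema.codebooks[col]

        def code(v, book=book, col=col):
            if pd.isna(v):
                return np.nan
            key = str(v)
            if key not in book:
                # tolerate already-encoded numeric input
                try:
                    fv = float(key)
                    if fv in set(book.values()) or fv == Schema.UNSEEN:
                        return fv
                except ValueError:
                    pass
                warnings.warn(f"unseen category {key!r} in {col!r}; "
                              f"mapped to reserved ordinal {Schema.UNSEEN}")
                return float(Schema.UNSEEN)
            return float(book[key])

        df[col] = df[col].map(code)
    return df


def encode_categoricals(cohort: Cohort, schema: Schema) -> Cohort:
    """Ordinal-encode categorical features of an in-memory cohort."""
    df = cohort.to_dataframe()
    for col, kind in schema.feature_types.items():
        if kind == "categorical" and col not in schema.codebooks:
            raise ValueError(f"categorical feature {col!r} has no codebook")
    df = encode_categoricals_df(df.astype(object), schema)
    out = []
    for r, (_, row) in zip(cohort, df.iterrows()):
        feats = {k: float(row[k]) for k in r.features}
        out.append(PatientRecord(r.patient_id, feats, r.time, r.event))
    return Cohort(out)


# ----------------------------------------------------------------------
# max-length policy and sampling

def compute_max_length(cohort: Cohort, percentile: float = 95.0) -> int:
    """Input length L: 1 + a percentile of per-patient feature counts.

    The +1 reserves the leading TASK slot. Uses linear interpolation
    between order statistics; capped at 1 + number of unique features.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    counts = [r.n_features for r in cohort]
    L = 1 + int(np.ceil(np.percentile(counts, percentile)))
    return min(L, 1 + len(cohort.feature_names))


def sample_and_pad(record: PatientRecord, L: int, vocab: Vocabulary,
                   rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode one record into a length-L row.

    Position 0 is ``[TASK, 1]``. If the record has more than L-1 features,
    a uniform without-replacement subsample is drawn (fresh each call when
    an ``rng`` is given); otherwise all features are used in vocabulary-id
    order, which makes inference deterministic.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    names = sorted(record.features, key=vocab.id_of)
    k = min(len(names), L - 1)
    if len(names) > L - 1:
        if rng is None:
            rng = np.random.default_rng(0)
        idx = rng.choice(len(names), size=k, replace=False)
        names = [names[i] for i in idx]
    token_ids = np.full(L, Vocabulary.PAD, dtype=int)
    values = np.zeros(L, dtype=float)
    pad_mask = np.ones(L, dtype=bool)
    token_ids[0] = Vocabulary.TASK
    values[0] = 1.0
    pad_mask[0] = False
    for j, name in enumerate(names, start=1):
        token_ids[j] = vocab.id_of(name)
        values[j] = record.features[name]
        pad_mask[j] = False
    return token_ids, values, pad_mask


def encode_cohort(cohort: Cohort, L: int, vocab: Vocabulary,
                  rng: np.random.Generator | None = None) -> EncodedBatch:
    """Encode every record of a cohort into an :class:`EncodedBatch`."""
    rows = [sample_and_pad(r, L, vocab, rng) for r in cohort]
    return EncodedBatch(
        token_ids=np.stack([r[0] for r in rows]),
        values=np.stack([r[1] for r in rows]),
        pad_mask=np.stack([r[2] for r in rows]),
    )
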
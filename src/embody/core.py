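"""Core data model for body-map analyses.

A *body map* is a raster of paint intensities (0 = no paint, 100 = fully
saturated) over a body silhouette, recorded separately for felt bodily
activation and deactivation.  Each subject produces one activation and one
deactivation map per emotional state.  The silhouette is partitioned into
five regions of interest (head, chest, abdomen, arms, legs); subjects carry
three z-scored schizotypy factor scores (interpersonal, cognitive/perceptual,
disorganized) harmonized across the two questionnaire versions (SPQ full
form and SPQ-B brief form).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ROI_LABELS",
    "ROI_NAMES",
    "EMOTIONS",
    "LOW_AROUSAL",
    "HIGH_AROUSAL",
    "EXCLUDED_AROUSAL",
    "POLARITIES",
    "EmotionInfo",
    "BodyMask",
    "BodyMap",
    "SubjectRecord",
    "MapCollection",
    "arousal_class",
    "load_mask",
    "save_mask",
    "load_collection",
    "save_collection",
    "harmonize_schizotypy",
]

#: ROI integer labels used on the mask grid (0 is background).
ROI_LABELS: dict[str, int] = {
    "head": 1,
    "chest": 2,
    "abdomen": 3,
    "arms": 4,
    "legs": 5,
}
ROI_NAMES: dict[int, str] = {v: k for k, v in ROI_LABELS.items()}

#: The twelve emotional states of the task: five basic emotions, six
#: non-basic emotions, and a neutral state.
EMOTIONS: tuple[str, ...] = (
    "anger",
    "fear",
    "disgust",
    "happiness",
    "sadness",
    "anxiety",
    "love",
    "depression",
    "pride",
    "shame",
    "jealousy",
    "neutral",
)

# Arousal grouping, taken from the hierarchical clustering of body-map
# similarity in the original task literature: sadness and depression form a
# clearly separated low-arousal cluster embodied as deactivation; happiness,
# love, pride, anger and fear form high-arousal clusters embodied as
# activation.  The middle-cluster emotions and the neutral state are excluded
# from congruency scoring.
LOW_AROUSAL: frozenset[str] = frozenset({"sadness", "depression"})
HIGH_AROUSAL: frozenset[str] = frozenset({"happiness", "love", "pride", "anger", "fear"})
EXCLUDED_AROUSAL: frozenset[str] = frozenset({"anxiety", "shame", "disgust", "jealousy"})

POLARITIES: tuple[str, str] = ("activation", "deactivation")

SCHIZOTYPY_FACTORS: tuple[str, ...] = ("interpersonal", "cognitive_perceptual", "disorganized")
INSTRUMENTS: tuple[str, str] = ("SPQ", "SPQ-B")


def arousal_class(emotion: str) -> str:
    """Return 'low', 'high', 'excluded' or 'neutral' for a known emotion."""
    if emotion not in EMOTIONS:
        raise ValueError(f"unknown emotion label: {emotion!r}")
    if emotion in LOW_AROUSAL:
        return "low"
    if emotion in HIGH_AROUSAL:
        return "high"
    if emotion == "neutral":
        return "neutral"
    return "excluded"


@dataclass(frozen=True)
class EmotionInfo:
    name: str
    arousal_class: str

    @classmethod
    def of(cls, name: str) -> "EmotionInfo":
        return cls(name, arousal_class(name))


@dataclass(frozen=True)
class BodyMask:
    """Silhouette + ROI label grid.

    ``grid`` holds integer labels in {0..5}; ``n_body_pixels`` is the count
    of in-silhouette (nonzero-label) pixels and is the denominator of the
    size metric.
    """

    grid: np.ndarray
    n_body_pixels: int = field(init=False)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if not np.issubdtype(grid.dtype, np.integer):
            if not np.all(grid == np.round(grid)):
                raise ValueError("mask grid must be integer-valued")
            grid = grid.astype(np.int64)
        bad = np.setdiff1d(np.unique(grid), np.arange(6))
        if bad.size:
            raise ValueError(f"illegal ROI label(s) in mask: {bad.tolist()}")
        for name, lab in ROI_LABELS.items():
            if not np.any(grid == lab):
                raise ValueError(f"empty ROI in mask: {name!r} (label {lab})")
        grid.setflags(write=False)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "n_body_pixels", int(np.count_nonzero(grid)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def body(self) -> np.ndarray:
        """Boolean in-silhouette indicator."""
        return self.grid > 0

    def roi(self, label: int | str) -> np.ndarray:
        """Boolean indicator for one ROI, by label or by name."""
        if isinstance(label, str):
            try:
                label = ROI_LABELS[label]
            except KeyError:
                raise ValueError(f"unknown ROI name: {label!r}") from None
        if label not in ROI_NAMES:
            raise ValueError(f"unknown ROI label: {label!r}")
        return self.grid == label


@dataclass(frozen=True)
class BodyMap:
    """One polarity raster for one subject x emotion.

    Intensities are dimensionless in [0, 100]; cells outside the silhouette
    must be zero.
    """

    subject_id: str
    emotion: str
    polarity: str
    grid: np.ndarray
    mask: BodyMask

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion label: {self.emotion!r}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}, got {self.polarity!r}")
        grid = np.asarray(self.grid, dtype=float)
        if grid.shape != self.mask.shape:
            raise ValueError(
                f"map grid {grid.shape} does not match mask {self.mask.shape}"
            )
        if not np.all(np.isfinite(grid)):
            raise ValueError("map grid contains non-finite values")
        if grid.min() < 0 or grid.max() > 100:
            raise ValueError("intensity out of range [0, 100]")
        n_outside = int(np.count_nonzero(grid[~self.mask.body]))
        if n_outside:
            raise ValueError(f"paint outside silhouette at {n_outside} pixel(s)")
        grid.setflags(write=False)
        object.__setattr__(self, "grid", grid)

    @property
    def painted(self) -> np.ndarray:
        """Boolean support of colored (intensity > 0) pixels."""
        return self.grid > 0

    def with_grid(self, grid: np.ndarray) -> "BodyMap":
        return replace(self, grid=grid)


@dataclass
class SubjectRecord:
    """Schizotypy factor scores for one subject.

    ``raw_factor_scores`` holds the instrument-native factor totals;
    ``z_factor_scores`` is filled by :func:`harmonize_schizotypy` (within
    instrument sub-sample, higher = more schizotypal).
    """

    subject_id: str
    instrument: str
    raw_factor_scores: dict[str, float]
    z_factor_scores: dict[str, float] | None = None
    demographics: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.instrument not in INSTRUMENTS:
            raise ValueError(f"instrument must be one of {INSTRUMENTS}, got {self.instrument!r}")
        missing = set(SCHIZOTYPY_FACTORS) - set(self.raw_factor_scores)
        if missing:
            raise ValueError(f"missing raw factor scores: {sorted(missing)}")


@dataclass
class MapCollection:
    """All maps of a study: (subject, emotion, polarity) -> BodyMap."""

    mask: BodyMask
    subjects: list[SubjectRecord]
    maps: dict[tuple[str, str, str], BodyMap]

    def __post_init__(self) -> None:
        for key, m in self.maps.items():
            if key != (m.subject_id, m.emotion, m.polarity):
                raise ValueError(f"map key {key} does not match map identity")
            if m.mask.shape != self.mask.shape:
                raise ValueError("map mask dimensions differ from collection mask")

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def get(self, subject_id: str, emotion: str, polarity: str) -> BodyMap:
        return self.maps[(subject_id, emotion, polarity)]

    def pair(self, subject_id: str, emotion: str) -> tuple[BodyMap, BodyMap]:
        """(activation, deactivation) pair for one subject x emotion."""
        return (
            self.maps[(subject_id, emotion, "activation")],
            self.maps[(subject_id, emotion, "deactivation")],
        )

    def __len__(self) -> int:
        return len(self.maps)


# ---------------------------------------------------------------------------
# I/O: delimited-text rasters and masks, CSV manifests and subject tables
# ---------------------------------------------------------------------------

def load_mask(path: str | Path) -> BodyMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    grid = np.loadtxt(path, dtype=np.int64, ndmin=2)
    return BodyMask(grid)


def save_mask(mask: BodyMask, path: str | Path) -> None:
    np.savetxt(path, mask.grid, fmt="%d")


def load_collection(manifest_path: str | Path, mask: BodyMask,
                    subjects_path: str | Path | None = None) -> MapCollection:
    """Load a map collection from a CSV manifest.

    The manifest must have columns subject_id, emotion, polarity,
    raster_path (relative paths resolved against the manifest's directory).
    Every raster is validated against the mask's dimensions, the [0, 100]
    intensity range and the silhouette support; duplicate keys are rejected.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, dtype=str)
    required = {"subject_id", "emotion", "polarity", "raster_path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest missing columns: {sorted(required - set(manifest.columns))}")
    keys = list(zip(manifest.subject_id, manifest.emotion, manifest.polarity))
    if len(keys) != len(set(keys)):
        dupes = pd.Series(keys).value_counts()
        raise ValueError(f"duplicate manifest keys: {dupes[dupes > 1].index.tolist()}")
    maps: dict[tuple[str, str, str], BodyMap] = {}
    for row in manifest.itertuples(index=False):
        raster = Path(row.raster_path)
        if not raster.is_absolute():
            raster = manifest_path.parent / raster
        grid = np.loadtxt(raster, ndmin=2)
        maps[(row.subject_id, row.emotion, row.polarity)] = BodyMap(
            row.subject_id, row.emotion, row.polarity, grid, mask
        )
    if subjects_path is not None:
        subjects = load_subjects(subjects_path)
    else:
        seen: list[str] = []
        for sid, _, _ in maps:
            if sid not in seen:
                seen.append(sid)
        subjects = [SubjectRecord(sid, "SPQ", dict.fromkeys(SCHIZOTYPY_FACTORS, 0.0))
                    for sid in seen]
    return MapCollection(mask, subjects, maps)


def save_collection(collection: MapCollection, out_dir: str | Path) -> Path:
    """Write rasters + manifest + mask + subjects under ``out_dir``.

    Returns the manifest path.  Rasters go to ``rasters/`` as delimited text
    with full float precision so a round-trip reproduces them exactly.
    """
    out_dir = Path(out_dir)
    raster_dir = out_dir / "rasters"
    raster_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (sid, emotion, polarity), m in collection.maps.items():
        rel = f"rasters/{sid}_{emotion}_{polarity}.txt"
        np.savetxt(out_dir / rel, m.grid, fmt="%.17g")
        rows.append({"subject_id": sid, "emotion": emotion,
                     "polarity": polarity, "raster_path": rel})
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    save_mask(collection.mask, out_dir / "mask.txt")
    save_subjects(collection.subjects, out_dir / "subjects.csv")
    return manifest_path


def load_subjects(path: str | Path) -> list[SubjectRecord]:
    """Read subject table CSV: subject_id,instrument,f_interpersonal,f_cogper,f_disorg[,...]."""
    df = pd.read_csv(path)
    col_map = {"f_interpersonal": "interpersonal",
               "f_cogper": "cognitive_perceptual",
               "f_disorg": "disorganized"}
    missing = {"subject_id", "instrument", *col_map} - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    extra = [c for c in df.columns if c not in {"subject_id", "instrument", *col_map}]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(SubjectRecord(
            subject_id=str(d["subject_id"]),
            instrument=str(d["instrument"]),
            raw_factor_scores={new: float(d[old]) for old, new in col_map.items()},
            demographics={c: d[c] for c in extra},
        ))
    return records


def save_subjects(subjects: Iterable[SubjectRecord], path: str | Path) -> None:
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id, "instrument": s.instrument,
               "f_interpersonal": s.raw_factor_scores["interpersonal"],
               "f_cogper": s.raw_factor_scores["cognitive_perceptual"],
               "f_disorg": s.raw_factor_scores["disorganized"]}
        row.update(s.demographics)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Schizotypy score harmonization
# ---------------------------------------------------------------------------

def harmonize_schizotypy(subjects: list[SubjectRecord]) -> list[SubjectRecord]:
    """Convert raw factor scores to z-scores within each instrument sub-sample.

    The full-form (SPQ) and brief-form (SPQ-B) factor totals live on
    different scales; standardizing each factor within its instrument
    sub-sample (sample SD, n-1 denominator) puts every subject on a common
    z-scale with higher scores indicating elevated schizotypy.  Input
    records are not mutated; harmonization of already-z-scored data is
    idempotent up to floating tolerance.
    """
    out = [copy.deepcopy(s) for s in subjects]
    for instrument in {s.instrument for s in out}:
        group = [s for s in out if s.instrument == instrument]
        if len(group) < 2:
            raise ValueError(f"need >=2 subjects in {instrument} sub-sample to z-score")
        for factor in SCHIZOTYPY_FACTORS:
            raw = np.array([s.raw_factor_scores[factor] for s in group], dtype=float)
            sd = raw.std(ddof=1)
            if sd == 0:
                raise ValueError(f"zero variance for factor {factor!r} in {instrument} sub-sample")
            z = (raw - raw.mean()) / sd
            for s, zi in zip(group, z):
                if s.z_factor_scores is None:
                    s.z_factor_scores = {}
                s.z_factor_scores[factor] = float(zi)
    return out


def subject_z_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Harmonized z-scores as a DataFrame indexed by subject_id."""
    rows = {}
    for s in subjects:
        if s.z_factor_scores is None:
            raise ValueError(f"subject {s.subject_id} has no z-scores; run harmonize_schizotypy")
        rows[s.subject_id] = {f"z_{f}": s.z_factor_scores[f] for f in SCHIZOTYPY_FACTORS}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df
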
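"""Input/output for activation series, thematic profiles and run configuration.

The raw object of analysis is a T x V activation matrix: T timepoints
(fMRI volumes, "moments") by V features (voxels, surface vertices, or any
continuous measurements), sampled every ``tr_seconds`` seconds. Series can be
read from a 4D NIfTI volume (with an optional 3D inclusion mask) or from a
plain delimited text matrix.

All files written or read by this package index timepoints 1-based; internal
arrays are 0-based numpy.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

logger = logging.getLogger("temposeq")

__all__ = [
    "ImageSeries",
    "RunConfig",
    "load_series",
    "save_profile",
    "load_profile",
    "load_config",
    "save_matrix",
    "load_matrix",
]


@dataclass
class ImageSeries:
    """A T x V activation matrix with acquisition metadata.

    Rows are timepoints in acquisition order; columns are features
    (voxels/vertices). ``tr_seconds`` is the sampling interval, so row ``t``
    (0-based) was acquired at time ``t * tr_seconds``.
    """

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"series must be 2-D (T x V), got shape {self.data.shape}")
        if self.n_timepoints < 2:
            raise ValueError(f"need at least 2 timepoints, got {self.n_timepoints}")
        if self.n_features < 3:
            raise ValueError(
                f"need at least 3 features for partial correlation, got {self.n_features}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def check_no_constant_rows(self) -> None:
        """Raise if any timepoint is constant across features.

        A constant row has zero variance across features and cannot enter a
        correlation; callers that can tolerate this pass an explicit
        allow-degenerate flag downstream instead of silencing the check here.
        """
        ptp = self.data.max(axis=1) - self.data.min(axis=1)
        bad = np.flatnonzero(ptp == 0)
        if bad.size:
            raise ValueError(
                f"timepoints {(bad + 1).tolist()} are constant across features "
                "(1-based); pass allow_degenerate=True to proceed"
            )


@dataclass
class RunConfig:
    """Settings for a full analysis run.

    Defaults follow the method's reference settings: keep the top 5% of
    association values as edges, 100 degree-preserving surrogates, motif
    lengths 4..11 timepoints, alpha 0.05, 100 Louvain restarts at resolution 1.
    """

    threshold_fraction: float = 0.05
    n_surrogates: int = 100
    motif_lengths: tuple[int, ...] = tuple(range(4, 12))
    alpha: float = 0.05
    rng_seed: int = 0
    louvain_restarts: int = 100
    gamma: float = 1.0
    swaps_per_edge: int = 10
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must be in (0, 1]")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        self.motif_lengths = tuple(int(n) for n in self.motif_lengths)
        if min(self.motif_lengths) < 2:
            raise ValueError("motif lengths must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.louvain_restarts < 1:
            raise ValueError("louvain_restarts must be >= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["motif_lengths"] = list(self.motif_lengths)
        return d


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML config file mirroring :class:`RunConfig`; kwargs override."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    if "motif_lengths" in raw and isinstance(raw["motif_lengths"], str):
        lo, hi = raw["motif_lengths"].split(":")
        raw["motif_lengths"] = tuple(range(int(lo), int(hi) + 1))
    raw.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _load_delimited(path: Path) -> np.ndarray:
    import pandas as pd

    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        frame = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    except Exception as exc:  # pandas raises many flavours for malformed text
        raise ValueError(f"could not parse delimited matrix {path}: {exc}") from exc
    del sep
    arr = frame.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"non-numeric cells in {path}")
    arr = arr.astype(float)
    if np.isnan(arr).any():
        raise ValueError(f"NaN cells in {path}; missing data is not supported")
    return arr


def load_series(
    path: str | Path,
    mask: str | Path | None = None,
    tr_seconds: float = 1.0,
    transpose: bool = False,
    allow_degenerate: bool = False,
    subject_id: str = "",
    condition: str = "",
) -> ImageSeries:
    """Load an activation series from a 4D NIfTI volume or a delimited matrix.

    NIfTI voxels are flattened in C order (last spatial axis fastest), so
    feature ``v`` of the output corresponds to
    ``np.unravel_index(v, vol.shape[:3])`` in voxel coordinates (after mask
    selection). A 3D ``mask`` keeps voxels where the mask is nonzero; its
    grid must match the volume's. Delimited input is rows=timepoints unless
    ``transpose`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes).lower()
    if ".nii" in suffixes:
        import nibabel as nib

        img = nib.load(str(path))
        vol = np.asarray(img.dataobj, dtype=float)
        if vol.ndim != 4:
            raise ValueError(f"expected a 4D NIfTI, got shape {vol.shape}")
        flat = vol.reshape(-1, vol.shape[3], order="C").T  # T x (X*Y*Z)
        if mask is not None:
            mimg = nib.load(str(Path(mask)))
            marr = np.asarray(mimg.dataobj)
            if marr.shape != vol.shape[:3]:
                raise ValueError(
                    f"mask shape {marr.shape} does not match volume grid {vol.shape[:3]}"
                )
            keep = marr.reshape(-1, order="C") != 0
            flat = flat[:, keep]
        data = flat
    else:
        if mask is not None:
            raise ValueError("mask is only supported for NIfTI input")
        data = _load_delimited(path)
        if transpose:
            data = data.T
    series = ImageSeries(
        data=data, tr_seconds=tr_seconds, subject_id=subject_id, condition=condition
    )
    if not allow_degenerate:
        series.check_no_constant_rows()
    logger.info(
        "loaded series %s: T=%d, V=%d, TR=%gs", path.name, series.n_timepoints,
        series.n_features, tr_seconds,
    )
    return series


def save_profile(profile, path: str | Path) -> None:
    """Write a thematic profile as a two-column TSV (timepoint, theme), 1-based.

    Header comment lines carry the modularity statistic q and the TR so a
    profile file is self-contained for downstream motif/rhythm/harmony runs.
    """
    labels = np.asarray(profile.labels, dtype=int)
    if labels.size == 0:
        raise ValueError("cannot save an empty profile")
    if (labels < 1).any():
        raise ValueError("theme labels must be integers >= 1")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# q\t{profile.q!r}\n")
        fh.write(f"# tr_seconds\t{profile.tr_seconds!r}\n")
        fh.write("timepoint\ttheme\n")
        for t, lab in enumerate(labels, start=1):
            fh.write(f"{t}\t{int(lab)}\n")


def load_profile(path: str | Path):
    """Read a profile written by :func:`save_profile`; round-trip identity."""
    from .themes import ThematicProfile

    path = Path(path)
    header: dict[str, float] = {}
    rows: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) != 2:
                    raise ValueError(f"malformed header line in {path}: {line!r}")
                header[parts[0]] = float(parts[1])
                continue
            parts = line.split("\t")
            if parts[0] == "timepoint":
                continue
            try:
                t, lab = int(parts[0]), int(parts[1])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"malformed profile row in {path}: {line!r}") from exc
            rows.append((t, lab))
    if not rows:
        raise ValueError(f"profile file {path} holds no timepoints")
    if "q" not in header or "tr_seconds" not in header:
        raise ValueError(f"profile file {path} is missing q/tr_seconds header")
    times = [t for t, _ in rows]
    if times != list(range(1, len(rows) + 1)):
        raise ValueError(f"timepoint index in {path} must run 1..T without gaps")
    labels = np.array([lab for _, lab in rows], dtype=int)
    if (labels < 1).any():
        raise ValueError("theme labels must be integers >= 1")
    return ThematicProfile(
        labels=labels,
        q=header["q"],
        tr_seconds=header["tr_seconds"],
    )


def save_matrix(values: np.ndarray, path: str | Path) -> None:
    """Write a dense matrix as TSV (no header)."""
    np.savetxt(path, np.asarray(values), delimiter="\t", fmt="%.17g")


def load_matrix(path: str | Path) -> np.ndarray:
    arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    if np.isnan(arr).any():
        raise ValueError(f"NaN cells in {path}")
    return arr


def configure_logging(level: int = logging.INFO) -> None:
    """Timestamped logging for CLI runs; library use leaves logging alone."""
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(level)
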
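"""Marker trajectory container, CSV IO, validation and gap filling.

Optical motion-capture trials are held as a :class:`MarkerTrajectorySet`:
a dense ``(n_frames, n_markers, 3)`` array of positions in metres with
``NaN`` marking missing samples, plus the capture rate and trial metadata.
The on-disk format is a long-form CSV dialect (``frame,marker,x_m,y_m,z_m``;
empty fields encode missing samples).

Gap filling follows the inter-correlation idea used for mocap
reconstruction: a gapped marker is regressed on the principal components of
the co-observed markers over the frames where everything is visible, and the
regression predicts the gap.  Short gaps with too few reference markers fall
back to linear interpolation.  Observed samples are never altered.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Markers the downstream gait pipeline cannot work without.
REQUIRED_MARKERS = ("LHEE", "RHEE", "LTOE", "RTOE", "SACR")


class MarkerError(ValueError):
    """Raised when required markers are absent or labels are inconsistent."""


class UnitsError(ValueError):
    """Raised for unknown or unsupported coordinate units."""


@dataclass
class TrialMeta:
    """Identity of one captured walk."""

    subject_id: str = ""
    group: str = ""
    speed: str = ""  # slow | comfortable | fast
    trial: int = 0


@dataclass
class Anthropometry:
    """Per-participant body measures used for dimensionless scaling.

    ``leg_length_m`` is L0, the spine-of-the-scaling; body mass is recorded
    for completeness but no spatiotemporal parameter here depends on it.
    """

    height_m: float
    body_mass_kg: float
    leg_length_m: float
    knee_width_m: float = 0.10
    ankle_width_m: float = 0.07

    def __post_init__(self) -> None:
        for name in ("height_m", "body_mass_kg", "leg_length_m",
                     "knee_width_m", "ankle_width_m"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.leg_length_m < self.height_m:
            raise ValueError("leg_length_m must be smaller than height_m")


@dataclass
class MarkerTrajectorySet:
    """Time-indexed 3D positions for the labelled markers of one trial."""

    sample_rate: float
    markers: list[str]
    positions: np.ndarray  # (n_frames, n_markers, 3), metres, NaN = missing
    meta: TrialMeta = field(default_factory=TrialMeta)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_markers, 3)")
        if self.positions.shape[1] != len(self.markers):
            raise ValueError("marker label count does not match positions")
        finite = np.isfinite(self.positions)
        partial = finite.any(axis=2) & ~finite.all(axis=2)
        if partial.any():
            raise ValueError("a sample must be fully observed or fully missing")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sample_rate

    def index(self, label: str) -> int:
        try:
            return self.markers.index(label)
        except ValueError:
            raise MarkerError(f"marker {label!r} not present") from None

    def get(self, label: str) -> np.ndarray:
        """Positions of one marker, shape ``(n_frames, 3)``."""
        return self.positions[:, self.index(label), :]

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_frames, n_markers)``; True where the sample is missing."""
        return ~np.isfinite(self.positions).all(axis=2)

    def copy(self) -> "MarkerTrajectorySet":
        return replace(self, positions=self.positions.copy(),
                       markers=list(self.markers))

    def validate_markers(self, required=REQUIRED_MARKERS) -> None:
        missing = [m for m in required if m not in self.markers]
        if missing:
            raise MarkerError(
                "required markers absent: " + ", ".join(sorted(missing)))


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_UNIT_SCALE = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}


def write_trial(t: MarkerTrajectorySet, path) -> None:
    """Write the long-form CSV dialect; missing samples become empty fields."""
    n, m = t.n_frames, len(t.markers)
    frame = np.repeat(np.arange(n), m)
    marker = np.tile(np.asarray(t.markers, dtype=object), n)
    xyz = t.positions.reshape(n * m, 3)
    df = pd.DataFrame({"frame": frame, "marker": marker,
                       "x_m": xyz[:, 0], "y_m": xyz[:, 1], "z_m": xyz[:, 2]})
    header = (f"# sample_rate_hz={t.sample_rate}"
              f" subject={t.meta.subject_id} group={t.meta.group}"
              f" speed={t.meta.speed} trial={t.meta.trial}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, na_rep="")


def read_trial(path, fmt: str = "csv", *, units: str = "m",
               sample_rate: float | None = None,
               required=REQUIRED_MARKERS) -> MarkerTrajectorySet:
    """Read a trial and validate units, labels and frame alignment.

    Parameters
    ----------
    fmt
        Only the documented CSV dialect is supported.
    units
        Coordinate units of the file (``m``/``mm``/``cm``); everything is
        converted to metres.  Missing samples are flagged, never zero-filled.
    sample_rate
        Overrides the header value if given.
    """
    if fmt != "csv":
        raise ValueError(f"unsupported trajectory format: {fmt!r}")
    try:
        scale = _UNIT_SCALE[units]
    except KeyError:
        raise UnitsError(f"unknown coordinate units: {units!r}") from None

    with open(path) as fh:
        first = fh.readline()
        meta = TrialMeta()
        rate = sample_rate
        if first.startswith("#"):
            kv = dict(tok.split("=", 1) for tok in first[1:].split() if "=" in tok)
            if rate is None and "sample_rate_hz" in kv:
                rate = float(kv["sample_rate_hz"])
            meta = TrialMeta(subject_id=kv.get("subject", ""),
                             group=kv.get("group", ""),
                             speed=kv.get("speed", ""),
                             trial=int(kv.get("trial", 0) or 0))
            body = fh.read()
        else:
            body = first + fh.read()
    if rate is None:
        raise ValueError("sample_rate not given and not present in file header")

    df = pd.read_csv(io.StringIO(body))
    expected = {"frame", "marker", "x_m", "y_m", "z_m"}
    if set(df.columns) != expected:
        raise ValueError(f"CSV columns must be {sorted(expected)}")

    markers = list(dict.fromkeys(df["marker"]))  # first-appearance order
    n = int(df["frame"].max()) + 1
    pos = np.full((n, len(markers), 3), np.nan)
    midx = {lab: j for j, lab in enumerate(markers)}
    rows = df["frame"].to_numpy(int)
    cols = df["marker"].map(midx).to_numpy(int)
    pos[rows, cols, :] = df[["x_m", "y_m", "z_m"]].to_numpy(float) * scale

    t = MarkerTrajectorySet(sample_rate=rate, markers=markers,
                            positions=pos, meta=meta)
    t.validate_markers(required)
    return t


# ---------------------------------------------------------------------------
# Gap filling
# ---------------------------------------------------------------------------

@dataclass
class GapFillReport:
    """Audit of what :func:`fill_gaps` did."""

    filled: list[tuple[str, int, int, str]] = field(default_factory=list)
    left_missing: list[tuple[str, int, int, str]] = field(default_factory=list)
    unreconstructable: list[str] = field(default_factory=list)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a 1-D mask as (start, stop) with stop exclusive."""
    idx = np.flatnonzero(np.diff(np.r_[0, mask.view(np.int8), 0]))
    return list(zip(idx[0::2], idx[1::2]))


def fill_gaps(t: MarkerTrajectorySet, max_gap_frames: int = 50,
              *, min_reference_markers: int = 3,
              interp_fallback_frames: int = 5,
              pca_variance: float = 1.0,
              ) -> tuple[MarkerTrajectorySet, GapFillReport]:
    """Reconstruct gaps from the inter-correlation of co-observed markers.

    For each gapped marker, reference markers observed on every frame of the
    gap and on enough common frames are assembled, reduced by PCA, and the
    gapped marker's coordinates are regressed on the scores over the frames
    where both are visible; the fit predicts the gap.  Gaps longer than
    ``max_gap_frames`` are left missing and reported.  Observed samples pass
    through bit-identical.
    """
    missing = t.missing_mask()
    valid_frac = 1 - missing.mean(axis=0)
    if (valid_frac >= 0.5).sum() < 3:
        raise ValueError("need at least 3 markers with >= 50% valid frames")

    out = t.copy()
    report = GapFillReport()
    for j, label in enumerate(t.markers):
        col = missing[:, j]
        if not col.any():
            continue
        if col.all():
            report.unreconstructable.append(label)
            continue
        for start, stop in _runs(col):
            gap_len = stop - start
            if gap_len > max_gap_frames:
                report.left_missing.append((label, start, stop, "gap too long"))
                continue
            gap = np.arange(start, stop)
            # references: other markers fully observed over the gap
            refs = [k for k in range(len(t.markers))
                    if k != j and not missing[gap, k].any()]
            train = np.flatnonzero(~col)
            if refs:
                ref_ok = ~missing[np.ix_(train, refs)].any(axis=1)
                train_ok = train[ref_ok]
            else:
                train_ok = np.array([], dtype=int)
            if len(refs) >= min_reference_markers and len(train_ok) >= 3 * len(refs):
                X = t.positions[:, refs, :].reshape(t.n_frames, -1)
                pred = _pca_regress(X[train_ok], t.positions[train_ok, j, :],
                                    X[gap], pca_variance)
                out.positions[gap, j, :] = pred
                report.filled.append((label, start, stop, "pca"))
            elif gap_len <= interp_fallback_frames and 0 < start and stop < t.n_frames \
                    and not col[start - 1] and (stop >= t.n_frames or not col[stop % t.n_frames]):
                lo, hi = t.positions[start - 1, j, :], t.positions[stop, j, :]
                w = (np.arange(1, gap_len + 1) / (gap_len + 1))[:, None]
                out.positions[gap, j, :] = lo * (1 - w) + hi * w
                report.filled.append((label, start, stop, "linear"))
            else:
                report.left_missing.append((label, start, stop,
                                            "insufficient references"))
    return out, report


def _pca_regress(X_train, y_train, X_pred, pca_variance):
    mu = X_train.mean(axis=0)
    Xc = X_train - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s.size and s[0] > 0:
        if pca_variance >= 1.0:  # numerical rank: keep every real component
            k = int((s > 1e-8 * s[0]).sum())
        else:
            var = s**2 / (s**2).sum()
            k = min(int(np.searchsorted(np.cumsum(var), pca_variance) + 1),
                    len(s))
    else:
        k = 1
    scores = Xc @ Vt[:k].T
    A = np.c_[scores, np.ones(len(scores))]
    coef, *_ = np.linalg.lstsq(A, y_train, rcond=None)
    scores_pred = (X_pred - mu) @ Vt[:k].T
    return np.c_[scores_pred, np.ones(len(scores_pred))] @ coef


# ---------------------------------------------------------------------------
# Travel frame
# ---------------------------------------------------------------------------

def travel_axis(t: MarkerTrajectorySet, pelvis_marker: str = "SACR",
                min_displacement_m: float = 0.5) -> np.ndarray:
    """Unit 2-D vector of the walking direction in the horizontal plane.

    Estimated from the net pelvis displacement so passes in either walkway
    direction become uniform once projected (travel is always +axis).
    """
    p = t.get(pelvis_marker)
    ok = np.isfinite(p).all(axis=1)
    if ok.sum() < 2:
        raise ValueError("pelvis marker has fewer than 2 observed frames")
    first, last = p[ok][0], p[ok][-1]
    d = (last - first)[:2]
    norm = float(np.hypot(*d))
    if norm < min_displacement_m:
        raise ValueError(
            f"pelvis displacement {norm:.3f} m below {min_displacement_m} m; "
            "no walking direction detectable")
    return d / norm
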
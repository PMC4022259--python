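"""Containers, CSV input and sampling-volume correction for dissolution data.

A dissolution test measures how much drug each dosage unit has released into
a stirred vessel at a sequence of sampling times.  Autosamplers withdraw a
fixed aliquot ``V_s`` at every time point from a vessel of original volume
``V_or``; unless the aliquot is replaced with fresh medium, both vessel
volume and drug mass are lost to sampling, so raw concentrations must be
corrected before they can be read as cumulative percent dissolved.

Two correction conventions are implemented behind a ``mode`` flag:

``"as-printed"``
    The form commonly printed in the dissolution literature.  With no
    replacement the released fraction at the *i*-th draw (1-based) is

        F_i = C_i * (V_or - (i-1) * V_s) / (Dose - sum_{j<i} C_j * V_s)

    and with replacement the volume term stays at ``V_or``.  The ``(i-1)``
    counts samples already withdrawn before the current draw, so the first
    time point needs no correction.

``"mass-balance"``
    The additive accounting of drug mass: drug currently in the vessel plus
    drug carried away by earlier aliquots, all over the dose,

        F_i = (C_i * V_i + sum_{j<i} C_j * V_s) / Dose,

    with ``V_i`` the vessel volume at draw *i*.  The two conventions agree
    at the first time point and whenever ``V_s = 0``, and they coincide as
    dissolution completes, but they differ mid-profile.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DissolutionBatch",
    "ProfileSummary",
    "DissolutionDataError",
    "VALUE_KINDS",
    "CORRECTION_MODES",
    "load_batch",
    "correct_profile",
    "correct_batch",
    "summarize",
]

logger = logging.getLogger(__name__)

VALUE_KINDS = ("concentration", "percent_dissolved")
CORRECTION_MODES = ("as-printed", "mass-balance")

#: Percent-dissolved values may overshoot 100 slightly from assay error.
PERCENT_UPPER = 110.0


class DissolutionDataError(ValueError):
    """Raised for invalid dissolution data or metadata."""


@dataclass
class DissolutionBatch:
    """One product's dissolution measurements on a shared time grid.

    Parameters
    ----------
    label : str
        Product/batch identifier.
    times : array of float
        Sampling times in minutes, strictly increasing, all > 0.
    units : 2-D array
        Measurements; rows are dosage units, columns align with `times`.
    value_kind : {"concentration", "percent_dissolved"}
        Whether `units` holds raw sampled concentrations (mass/volume) or
        cumulative percent dissolved.
    dose : float, optional
        Label claim drug mass per unit; required to correct concentrations.
    v_original : float, optional
        Original receptacle volume ``V_or`` (same volume unit as `v_sample`).
    v_sample : float
        Aliquot volume ``V_s`` withdrawn at each sampling time.
    replaced : bool
        True when each aliquot is replaced with an equal volume of medium.
    unit_labels : sequence of str, optional
        Row labels; defaults to ``unit_1`` ... ``unit_N``.
    """

    label: str
    times: np.ndarray
    units: np.ndarray
    value_kind: str
    dose: float | None = None
    v_original: float | None = None
    v_sample: float = 0.0
    replaced: bool = False
    unit_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.units = np.atleast_2d(np.asarray(self.units, dtype=float))
        if self.value_kind not in VALUE_KINDS:
            raise DissolutionDataError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        if self.times.ndim != 1 or self.times.size == 0:
            raise DissolutionDataError("times must be a non-empty 1-D array")
        if np.any(self.times <= 0):
            raise DissolutionDataError("times must be strictly positive (t = 0 is never stored)")
        if np.any(np.diff(self.times) <= 0):
            raise DissolutionDataError("times not strictly increasing")
        if self.units.shape[0] < 1:
            raise DissolutionDataError("at least one dosage unit is required")
        if self.units.shape[1] != self.times.size:
            raise DissolutionDataError(
                f"unit matrix has {self.units.shape[1]} columns but {self.times.size} times"
            )
        if np.any(~np.isfinite(self.units)):
            raise DissolutionDataError("unit matrix contains missing or non-finite cells")
        if np.any(self.units < 0):
            raise DissolutionDataError("negative measurements are not valid")
        if self.value_kind == "percent_dissolved" and np.any(self.units > PERCENT_UPPER):
            raise DissolutionDataError(
                f"percent-dissolved values must lie in [0, {PERCENT_UPPER:g}]"
            )
        if not self.unit_labels:
            self.unit_labels = tuple(f"unit_{i + 1}" for i in range(self.units.shape[0]))
        elif len(self.unit_labels) != self.units.shape[0]:
            raise DissolutionDataError("unit_labels length does not match number of units")

    @property
    def n_units(self) -> int:
        return self.units.shape[0]

    @property
    def n_times(self) -> int:
        return self.times.size

    def mean_profile(self) -> np.ndarray:
        """Per-time-point mean across dosage units."""
        return self.units.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with ``time_<min>`` columns and one row per unit."""
        cols = [f"time_{t:g}" for t in self.times]
        return pd.DataFrame(self.units, index=list(self.unit_labels), columns=cols)


@dataclass
class ProfileSummary:
    """Per-time-point mean, sample SD and CV of percent dissolved.

    `sd_pct`/`cv_pct` are NaN wherever undefined: for a single-unit batch
    (no within-batch spread estimable) and, for CV, where the mean is zero
    with nonzero SD.  `n_units` records the sample size behind the SDs.
    """

    times: np.ndarray
    mean_pct: np.ndarray
    sd_pct: np.ndarray
    cv_pct: np.ndarray
    n_units: int

    def __post_init__(self) -> None:
        n = self.times.size
        for name in ("mean_pct", "sd_pct", "cv_pct"):
            if getattr(self, name).size != n:
                raise DissolutionDataError(f"{name} length does not match times")


def _parse_time_header(name: str) -> float | None:
    """Parse a column header as a sampling time; None if not time-like."""
    token = str(name).strip()
    for prefix in ("time_", "time", "t_"):
        if token.lower().startswith(prefix):
            token = token[len(prefix):]
            break
    try:
        return float(token)
    except ValueError:
        return None


def load_batch(
    source: str | IO[str],
    *,
    value_kind: str,
    label: str = "batch",
    dose: float | None = None,
    v_original: float | None = None,
    v_sample: float = 0.0,
    replaced: bool = False,
) -> DissolutionBatch:
    """Read a dissolution batch from CSV text.

    The header row gives the sampling times (``time_10,time_15,...`` or bare
    numbers); each subsequent row is one dosage unit.  An optional first
    column holds unit labels.  A ``time_0`` column is accepted but dropped
    with a logged notice, since every downstream rule excludes t = 0.

    Raises
    ------
    DissolutionDataError
        For non-increasing times, ragged rows or blank cells (named by
        row/column), negative values, or missing vessel metadata when
        `value_kind` is ``"concentration"``.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    try:
        # header=None so pandas does not rename duplicated time columns,
        # which would mask a duplicated-time validation error
        raw = pd.read_csv(source, header=None, skip_blank_lines=True, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DissolutionDataError(f"could not parse CSV: {exc}") from exc
    if raw.shape[0] < 2 or raw.shape[1] == 0:
        raise DissolutionDataError("CSV has no data rows")
    df = raw.iloc[1:].reset_index(drop=True)
    df.columns = list(raw.iloc[0])

    headers = [str(h) for h in df.columns]
    parsed = [_parse_time_header(h) for h in headers]
    unit_labels: tuple[str, ...] = ()
    if parsed[0] is None:
        unit_labels = tuple(str(v) for v in df.iloc[:, 0])
        df = df.iloc[:, 1:]
        headers, parsed = headers[1:], parsed[1:]
    bad = [h for h, p in zip(headers, parsed) if p is None]
    if bad:
        raise DissolutionDataError(f"columns {bad} are not time columns")
    times = np.asarray(parsed, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise DissolutionDataError("times not strictly increasing")

    # blank / non-numeric cells: name the offending row and column
    columns = []
    for j in range(df.shape[1]):
        numeric = pd.to_numeric(df.iloc[:, j], errors="coerce")
        missing = numeric.isna()
        if missing.any():
            i = int(np.argmax(missing.to_numpy()))
            row_name = unit_labels[i] if unit_labels else f"row {i + 1}"
            raise DissolutionDataError(
                f"blank or non-numeric cell at {row_name}, column {headers[j]!r}"
            )
        columns.append(numeric.to_numpy(dtype=float))
    values = np.column_stack(columns)

    if np.any(times == 0):
        keep = times != 0
        logger.info("dropping %d t=0 column(s); comparisons exclude t = 0", int((~keep).sum()))
        times, values = times[keep], values[:, keep]

    if value_kind == "concentration" and (dose is None or v_original is None):
        raise DissolutionDataError(
            "dose and v_original metadata are required for concentration data"
        )
    return DissolutionBatch(
        label=label,
        times=times,
        units=values,
        value_kind=value_kind,
        dose=dose,
        v_original=v_original,
        v_sample=v_sample,
        replaced=replaced,
        unit_labels=unit_labels,
    )


def correct_profile(
    raw: np.ndarray,
    dose: float,
    v_or: float,
    v_s: float,
    replaced: bool,
    mode: str = "as-printed",
) -> np.ndarray:
    """Convert sampled concentrations to cumulative percent dissolved.

    Parameters
    ----------
    raw : array
        Concentrations, shape ``(n_times,)`` or ``(n_units, n_times)``,
        ordered by sampling time.
    dose, v_or, v_s : float
        Drug mass per unit, original vessel volume, aliquot volume.
    replaced : bool
        Whether each aliquot is replaced with fresh medium.
    mode : {"as-printed", "mass-balance"}
        Correction convention; see the module docstring.

    Returns
    -------
    ndarray
        Percent dissolved, same shape as `raw`.

    Raises
    ------
    DissolutionDataError
        If the running as-printed denominator (dose minus drug removed by
        earlier aliquots) drops to zero or below — clipping would silently
        fabricate data.
    """
    if mode not in CORRECTION_MODES:
        raise DissolutionDataError(f"unknown correction mode {mode!r}")
    if dose <= 0 or v_or <= 0 or v_s < 0:
        raise DissolutionDataError("dose and v_or must be positive, v_s non-negative")
    conc = np.atleast_2d(np.asarray(raw, dtype=float))
    n_times = conc.shape[1]
    if not replaced and v_s * (n_times - 1) >= v_or:
        raise DissolutionDataError("cumulative sampled volume exhausts the vessel")

    pct = np.empty_like(conc)
    removed = np.zeros(conc.shape[0])  # drug mass carried away by earlier aliquots
    for i in range(n_times):
        vol = v_or if replaced else v_or - i * v_s
        if mode == "as-printed":
            denom = dose - removed
            if np.any(denom <= 0):
                raise DissolutionDataError(
                    f"correction denominator non-positive at time index {i + 1}: "
                    "drug removed by sampling reaches the dose"
                )
            pct[:, i] = 100.0 * conc[:, i] * vol / denom
        else:
            pct[:, i] = 100.0 * (conc[:, i] * vol + removed) / dose
        removed = removed + conc[:, i] * v_s
    return pct if np.asarray(raw).ndim == 2 else pct[0]


def correct_batch(batch: DissolutionBatch, mode: str = "as-printed") -> DissolutionBatch:
    """Return a percent-dissolved copy of a concentration batch."""
    if batch.value_kind != "concentration":
        raise DissolutionDataError("batch is already percent_dissolved")
    if batch.dose is None or batch.v_original is None:
        raise DissolutionDataError("batch lacks dose/v_original metadata")
    pct = correct_profile(
        batch.units, batch.dose, batch.v_original, batch.v_sample, batch.replaced, mode
    )
    return DissolutionBatch(
        label=batch.label,
        times=batch.times.copy(),
        units=np.clip(pct, 0.0, PERCENT_UPPER),
        value_kind="percent_dissolved",
        dose=batch.dose,
        v_original=batch.v_original,
        v_sample=batch.v_sample,
        replaced=batch.replaced,
        unit_labels=batch.unit_labels,
    )


def summarize(batch: DissolutionBatch) -> ProfileSummary:
    """Per-time-point mean, sample SD (n-1 denominator) and CV.

    CV is ``100 * sd / mean``; where the mean is zero the CV is 0 when the
    SD is also zero and NaN (undefined) otherwise — never infinity.  A
    single-unit batch gets NaN SD/CV arrays.
    """
    if batch.value_kind != "percent_dissolved":
        raise DissolutionDataError("summarize requires percent_dissolved data; correct first")
    mean = batch.units.mean(axis=0)
    if batch.n_units < 2:
        sd = np.full_like(mean, np.nan)
        cv = np.full_like(mean, np.nan)
    else:
        sd = batch.units.std(axis=0, ddof=1)
        cv = np.full_like(mean, np.nan)
        pos = mean > 0
        cv[pos] = 100.0 * sd[pos] / mean[pos]
        cv[(~pos) & (sd == 0)] = 0.0
    return ProfileSummary(
        times=batch.times.copy(), mean_pct=mean, sd_pct=sd, cv_pct=cv, n_units=batch.n_units
    )
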
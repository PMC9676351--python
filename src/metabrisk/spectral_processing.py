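"""Spectral preprocessing: bucketing, water exclusion, PQN, drift removal.

The downstream models consume a samples x bins feature matrix obtained by
integrating each 1D spectrum over fixed 0.02 ppm buckets between 0.2 and
10.0 ppm, dropping the residual-water window (4.42-5.10 ppm, 34 buckets,
leaving 456), normalizing each sample by its probabilistic quotient against
a reference spectrum, and removing the linear acquisition-date trend that a
decade-long acquisition window imprints on every bucket.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

PULSE_SEQUENCES = ("NOESY1D", "CPMG", "DIFFUSION")

_ALIGN_TOL = 1e-9


@dataclass
class Spectrum:
    """A frequency-domain 1D NMR trace.

    ``ppm`` must be strictly monotone; intensities share its length.  The
    trace is tagged with the pulse sequence that produced it (NOESY1D
    detects all molecular species, CPMG small metabolites, diffusion-edited
    macromolecules) and the acquisition date used for drift modelling.
    """

    sample_id: str
    pulse_sequence: str
    ppm: np.ndarray
    intensity: np.ndarray
    acquisition_date: date

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise InputError("ppm and intensity must be 1-D vectors of equal length")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InputError("ppm axis must be strictly monotone")
        if self.pulse_sequence not in PULSE_SEQUENCES:
            raise InputError(f"unknown pulse sequence {self.pulse_sequence!r}")

    def ascending(self) -> "Spectrum":
        """Return a copy with the ppm axis ascending."""
        if self.ppm[0] < self.ppm[-1]:
            return self
        return replace(self, ppm=self.ppm[::-1].copy(), intensity=self.intensity[::-1].copy())


@dataclass(frozen=True)
class BinningConfig:
    """Bucket grid: [lo, hi) buckets of fixed width tiling ``range_ppm``.

    Exclusion regions must be aligned to the bucket grid (no partial-bucket
    removal): their endpoints sit on ``range_ppm[0] + k * bin_width_ppm``.
    """

    range_ppm: tuple[float, float] = (0.2, 10.0)
    bin_width_ppm: float = 0.02
    exclusion_regions: tuple[tuple[float, float], ...] = ((4.42, 5.10),)

    def __post_init__(self) -> None:
        lo, hi = self.range_ppm
        if not (lo < hi) or self.bin_width_ppm <= 0:
            raise ConfigurationError("invalid range or bin width")
        if abs(round((hi - lo) / self.bin_width_ppm) - (hi - lo) / self.bin_width_ppm) > _ALIGN_TOL:
            raise ConfigurationError("range span must be an integer number of bins")
        for elo, ehi in self.exclusion_regions:
            if ehi <= elo:
                raise ConfigurationError(f"empty exclusion region ({elo}, {ehi})")
            for edge in (elo, ehi):
                k = (edge - lo) / self.bin_width_ppm
                if abs(k - round(k)) > 1e-6:
                    raise ConfigurationError(
                        f"exclusion edge {edge} not aligned to the bin grid "
                        f"(origin {lo}, width {self.bin_width_ppm})"
                    )

    @property
    def n_bins_total(self) -> int:
        lo, hi = self.range_ppm
        return int(round((hi - lo) / self.bin_width_ppm))

    def bin_edges_ascending(self) -> np.ndarray:
        lo, hi = self.range_ppm
        edges = lo + self.bin_width_ppm * np.arange(self.n_bins_total + 1)
        return np.round(edges, 9)


@dataclass
class FeatureMatrix:
    """Samples x retained-bin matrix with bin-edge and date metadata.

    ``values`` is a DataFrame indexed by sample id whose columns follow
    ``bin_edges`` (descending ppm, NMR display convention, labelled
    ``"{lo:.2f}_{hi:.2f}"``).
    """

    values: pd.DataFrame
    bin_edges: list[tuple[float, float]]
    acquisition_dates: pd.Series
    pulse_sequence: str = "NOESY1D"

    def __post_init__(self) -> None:
        if len(self.bin_edges) != self.values.shape[1]:
            raise InputError("bin_edges must match the number of columns")
        self.acquisition_dates = self.acquisition_dates.reindex(self.values.index)
        if self.acquisition_dates.isna().any():
            missing = list(self.values.index[self.acquisition_dates.isna()])
            raise InputError(f"missing acquisition dates for samples {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(), list(self.bin_edges),
            self.acquisition_dates.copy(), self.pulse_sequence,
        )


def bin_label(lo: float, hi: float) -> str:
    return f"{lo:.2f}_{hi:.2f}"


def _cumulative_integral(spectrum: Spectrum):
    s = spectrum.ascending()
    F = np.concatenate([[0.0], cumulative_trapezoid(s.intensity, s.ppm)])
    return s.ppm, F


def integrate_interval(spectrum: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of the spectrum over [lo, hi]."""
    x, F = _cumulative_integral(spectrum)
    if lo < x[0] - _ALIGN_TOL or hi > x[-1] + _ALIGN_TOL:
        raise InputError(
            f"spectrum [{x[0]:g}, {x[-1]:g}] ppm does not cover [{lo:g}, {hi:g}]"
        )
    flo, fhi = np.interp([lo, hi], x, F)
    return float(fhi - flo)


def bucket_spectrum(
    spectrum: Spectrum, config: BinningConfig = BinningConfig()
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Integrate a spectrum over the bucket grid.

    Returns one trapezoidal integral per [lo, hi) bucket, in descending-ppm
    order, together with the matching bucket edges.  Raises
    :class:`InputError` naming the uncovered interval if the spectrum does
    not span the configured range.
    """
    x, F = _cumulative_integral(spectrum)
    lo, hi = config.range_ppm
    if x[0] > lo + _ALIGN_TOL or x[-1] < hi - _ALIGN_TOL:
        miss = []
        if x[0] > lo + _ALIGN_TOL:
            miss.append(f"[{lo:g}, {x[0]:g}]")
        if x[-1] < hi - _ALIGN_TOL:
            miss.append(f"[{x[-1]:g}, {hi:g}]")
        raise InputError(
            f"spectrum {spectrum.sample_id} does not cover {' and '.join(miss)} ppm"
        )
    edges = config.bin_edges_ascending()
    Fe = np.interp(edges, x, F)
    values = np.diff(Fe)  # ascending bins
    pairs = list(zip(edges[:-1], edges[1:]))
    # descending-ppm display order
    return values[::-1].copy(), [(float(a), float(b)) for a, b in pairs[::-1]]


def apply_exclusions(
    values: np.ndarray,
    bin_edges: Sequence[tuple[float, float]],
    config: BinningConfig = BinningConfig(),
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Drop every bucket fully contained in an exclusion region.

    Bucket order is otherwise preserved.  Exclusion regions are validated
    for grid alignment by :class:`BinningConfig`, so containment is exact.
    """
    keep = np.ones(len(bin_edges), dtype=bool)
    for i, (lo, hi) in enumerate(bin_edges):
        for elo, ehi in config.exclusion_regions:
            if lo >= elo - _ALIGN_TOL and hi <= ehi + _ALIGN_TOL:
                keep[i] = False
    kept_edges = [e for e, k in zip(bin_edges, keep) if k]
    return np.asarray(values)[keep], kept_edges


def build_feature_matrix(
    spectra: Iterable[Spectrum], config: BinningConfig = BinningConfig()
) -> FeatureMatrix:
    """Bucket + exclude a set of same-pulse-sequence spectra into a matrix."""
    spectra = list(spectra)
    if not spectra:
        raise InputError("no spectra supplied")
    seqs = {s.pulse_sequence for s in spectra}
    if len(seqs) > 1:
        raise InputError(f"mixed pulse sequences in one matrix: {sorted(seqs)}")
    rows, ids, dates = [], [], []
    kept_edges = None
    for s in spectra:
        vals, edges = bucket_spectrum(s, config)
        vals, edges = apply_exclusions(vals, edges, config)
        if kept_edges is None:
            kept_edges = edges
        rows.append(vals)
        ids.append(s.sample_id)
        dates.append(s.acquisition_date)
    df = pd.DataFrame(
        np.vstack(rows), index=ids, columns=[bin_label(*e) for e in kept_edges]
    )
    return FeatureMatrix(
        df, kept_edges, pd.Series(dates, index=ids), spectra[0].pulse_sequence
    )


def pqn_normalize(
    matrix: FeatureMatrix,
    reference: np.ndarray | None = None,
    reference_ids: Sequence[str] | None = None,
    area_normalize: bool = True,
) -> FeatureMatrix:
    """Probabilistic quotient normalization.

    Each sample is first total-area normalized (optional), then divided by
    the median over buckets of the quotient sample/reference.  When no
    explicit reference vector is given the reference is the median spectrum
    of ``reference_ids`` (default: all samples) after area normalization.
    Buckets where the reference is zero are excluded from the quotient
    median (the count is logged).
    """
    X = matrix.values.to_numpy(dtype=float).copy()
    sums = X.sum(axis=1)
    if np.any(sums == 0):
        bad = list(matrix.values.index[sums == 0])
        raise InputError(f"all-zero sample rows: {bad}")
    if area_normalize:
        X = X / sums[:, None]
    if reference is None:
        if reference_ids is None:
            ref_rows = X
        else:
            pos = [matrix.values.index.get_loc(i) for i in reference_ids]
            ref_rows = X[pos]
        reference = np.median(ref_rows, axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (X.shape[1],):
        raise InputError("reference length must equal the number of buckets")
    usable = reference > 0
    n_zero = int((~usable).sum())
    if n_zero:
        logger.warning("PQN: %d zero reference buckets excluded from quotients", n_zero)
    if not usable.any():
        raise InputError("reference spectrum has no positive buckets")
    quotients = X[:, usable] / reference[usable]
    med = np.median(quotients, axis=1)
    if np.any(med == 0):
        raise InputError("zero median quotient for at least one sample")
    out = matrix.copy()
    out.values.iloc[:, :] = X / med[:, None]
    return out


def correct_technical_drift(matrix: FeatureMatrix) -> FeatureMatrix:
    """Remove the linear acquisition-date trend from every bucket.

    Per bucket, intensity is regressed (OLS) on days since the earliest
    sample; the value is replaced by residual + bucket mean, so bucket means
    are preserved exactly and a second application is a no-op.
    """
    dates = pd.to_datetime(matrix.acquisition_dates)
    t = (dates - dates.min()).dt.days.to_numpy(dtype=float)
    if np.all(t == t[0]):
        warnings.warn("all samples share one acquisition date; drift correction is a no-op")
        return matrix.copy()
    tc = t - t.mean()
    X = matrix.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    slope = tc @ Xc / (tc @ tc)
    out = matrix.copy()
    out.values.iloc[:, :] = X - np.outer(tc, slope)
    return out


# ---------------------------------------------------------------------------
# I/O

def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    pd.DataFrame({"ppm": spectrum.ppm, "intensity": spectrum.intensity}).to_csv(
        path, index=False, float_format="%.8g"
    )


def read_spectrum_csv(path, sample_id, pulse_sequence, acquisition_date) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(
        sample_id=sample_id,
        pulse_sequence=pulse_sequence,
        ppm=df["ppm"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        acquisition_date=acquisition_date,
    )


def write_feature_matrix(matrix: FeatureMatrix, values_path, sidecar_path) -> None:
    matrix.values.to_csv(values_path, index_label="sample_id", float_format="%.10g")
    pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "pulse_sequence": matrix.pulse_sequence,
            "acquisition_date": [d.isoformat() for d in matrix.acquisition_dates],
        }
    ).to_csv(sidecar_path, index=False)


def read_feature_matrix(values_path, sidecar_path) -> FeatureMatrix:
    df = pd.read_csv(values_path, index_col="sample_id")
    side = pd.read_csv(sidecar_path)
    edges = []
    for col in df.columns:
        lo, hi = col.split("_")
        edges.append((float(lo), float(hi)))
    dates = pd.Series(
        [date.fromisoformat(d) for d in side["acquisition_date"]],
        index=side["sample_id"].tolist(),
    )
    return FeatureMatrix(df, edges, dates, side["pulse_sequence"].iloc[0])
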
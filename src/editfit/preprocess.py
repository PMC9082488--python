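"""Preprocessing chain: raw transients -> aligned, averaged, water-filtered
difference spectra plus the processed water reference.

Order of operations (each step optional via :class:`PreprocessConfig`):

1. eddy-current correction of all FIDs using the water-reference phase;
2. frequency-and-phase registration of the transients, separately within
   each sub-spectrum set;
3. weighted averaging (weights inversely proportional to the squared
   deviation from the pointwise-median transient);
4. pairwise sub-spectrum alignment (HERMES: water region for B->D, 2-ppm
   tNAA for C->D, 3.2-ppm tCho for A->C; MEGA-PRESS: tNAA region of the
   difference);
5. MEGA subtraction / HERMES Hadamard combination;
6. HSVD removal of residual water components;
7. apodization, zero-filling and FFT.

Registration solves the time-domain least-squares problem
``min_{df, phi} sum_t |s(t) e^{i(2 pi df t + phi)} - ref(t)|^2`` exactly:
for fixed ``df`` the optimal phase has a closed form, reducing the problem
to maximizing ``|H(df)|`` with ``H(df) = sum_t s(t) conj(ref(t))
e^{i 2 pi df t}``, which is located on a zero-padded FFT grid and refined
by parabolic interpolation.  This evaluates the same objective as a
derivative-free search but vectorizes across transients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg
import scipy.optimize

from .signal_model import (
    AcquisitionParams,
    Fid,
    Spectrum,
    hadamard_combine,
    mega_difference,
    to_spectrum,
)
from .synthetic_cohort import RawScan, default_catalog

__all__ = [
    "RegistrationResult",
    "PreprocessConfig",
    "ProcessedScan",
    "eddy_correct",
    "register_transients",
    "weighted_average",
    "align_subspectra",
    "hsvd_filter",
    "preprocess_scan",
]

# ppm intervals whose integrated magnitude is minimized in pairwise
# sub-spectrum alignment; kept tight around the target signal so tails of
# co-edited resonances (GABA+/MM at 3.0) cannot drive the optimization
ALIGN_REGIONS = {
    "water": (4.2, 5.2),
    "tNAA": (1.95, 2.07),
    "tCho": (3.15, 3.25),
}

# Pairwise corrections are bounded tightly: transient registration plus
# the interleaved acquisition order leave only sub-Hz, few-degree
# residual misalignment between sub-spectra, and the bound also caps the
# noise-driven scatter of the estimate (the phase information carried by
# one narrow region of a single averaged sub-spectrum is limited).
ALIGN_BOUNDS_HZ = 3.0  # the region frequency estimate is sharply determined
ALIGN_BOUNDS_DEG = 3.0  # the region phase estimate is noise-limited


@dataclass
class RegistrationResult:
    """Per-transient corrections applied by :func:`register_transients`."""

    shifts_hz: np.ndarray
    phases_deg: np.ndarray
    reference: str = "pointwise median across transients"
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.weights is not None:
            w = np.asarray(self.weights, float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("weights must be >= 0 and sum to 1")


def _water_phase(water: Fid) -> np.ndarray:
    """Unwrapped phase of the water FID (zero-magnitude samples carry the
    previous defined phase)."""
    w = water.samples
    mag = np.abs(w)
    phase = np.angle(np.where(mag > 0, w, 1.0))
    if np.any(mag == 0):
        warnings.warn("zero-magnitude water samples; carrying previous phase")
        idx = np.where(mag > 0, np.arange(len(w)), -1)
        np.maximum.accumulate(idx, out=idx)
        phase = np.where(idx >= 0, phase[np.maximum(idx, 0)], 0.0)
    return np.unwrap(phase)


def eddy_correct(fid: Fid, water: Fid) -> Fid:
    """Klose-style eddy-current correction: remove the unwrapped phase of
    the water FID from ``fid``.  Water corrected by itself becomes purely
    real and non-negative wherever it has magnitude."""
    if len(fid.samples) != len(water.samples):
        raise ValueError("fid and water must have equal length")
    phase = _water_phase(water)
    return Fid(fid.samples * np.exp(-1j * phase), fid.acq, fid.label)


def _median_reference(mat: np.ndarray) -> np.ndarray:
    return np.median(mat.real, axis=0) + 1j * np.median(mat.imag, axis=0)


def _estimate_shift_phase(
    mat: np.ndarray,
    ref: np.ndarray,
    dt: float,
    max_shift_hz: float = 20.0,
    pad: int = 4096,
) -> Tuple[np.ndarray, np.ndarray]:
    """Exact two-parameter registration of each row of ``mat`` to ``ref``
    (see module docstring).  Returns (shifts_hz, phases_rad) such that
    ``row * exp(i(2 pi df t + phi))`` best matches ``ref``."""
    n, nw = mat.shape
    h = mat * np.conj(ref)[None, :]
    # F[k] = sum_t h(t) e^{-i 2 pi f_k t} = H(-f_k)
    F = np.fft.fft(h, n=pad, axis=1)
    freqs = np.fft.fftfreq(pad, d=dt)
    ok = np.abs(freqs) <= max_shift_hz
    mag2 = np.abs(F) ** 2
    mag2[:, ~ok] = -1.0
    k = np.argmax(mag2, axis=1)
    km, kp = (k - 1) % pad, (k + 1) % pad
    rows = np.arange(n)
    y0, ym, yp = mag2[rows, k], mag2[rows, km], mag2[rows, kp]
    denom = ym - 2 * y0 + yp
    frac = np.where(np.abs(denom) > 0, 0.5 * (ym - yp) / np.where(denom == 0, 1, denom), 0.0)
    frac = np.clip(frac, -0.5, 0.5)
    df_grid = 1.0 / (pad * dt)
    f_peak = freqs[k] + frac * df_grid
    shifts = -f_peak  # H evaluated at -f_k
    # exact H at the refined shift -> closed-form optimal phase
    t = np.arange(nw) * dt
    H = np.einsum("ij,ij->i", h, np.exp(1j * 2 * np.pi * shifts[:, None] * t[None, :]))
    phases = -np.angle(H)
    return shifts, phases


def register_transients(
    transients: Sequence[Fid],
    cfg: Optional[Mapping] = None,
) -> Tuple[List[Fid], RegistrationResult]:
    """Frequency-and-phase correction of individual transients against a
    robust (pointwise median) reference, iterated with the reference
    rebuilt from the corrected transients."""
    cfg = dict(cfg or {})
    fit_window_ms = float(cfg.get("fit_window_ms", 200.0))
    n_iter = int(cfg.get("max_iter", 2))
    if len(transients) < 2:
        raise ValueError("need at least 2 transients")
    acq = transients[0].acq
    mat = np.array([tr.samples for tr in transients])
    if not np.all(np.isfinite(mat)):
        raise ValueError("non-finite samples in transients")
    dt = acq.dwell_time
    nw = max(8, min(mat.shape[1], int(round(fit_window_ms / 1000.0 / dt))))
    t_full = np.arange(mat.shape[1]) * dt
    total_shift = np.zeros(len(transients))
    total_phase = np.zeros(len(transients))
    for _ in range(n_iter):
        ref = _median_reference(mat[:, :nw])
        shifts, phases = _estimate_shift_phase(mat[:, :nw], ref, dt)
        mat = mat * np.exp(
            1j * (2 * np.pi * shifts[:, None] * t_full[None, :] + phases[:, None])
        )
        total_shift += shifts
        total_phase += phases
    out = [
        Fid(row, acq, tr.label) for row, tr in zip(mat, transients)
    ]
    return out, RegistrationResult(total_shift, np.rad2deg(total_phase))


def weighted_average(transients: Sequence[Fid]) -> Fid:
    """Average aligned transients with weights ``w_n ~ 1/d_n^2`` where
    ``d_n`` is the squared deviation of transient n from the pointwise
    median; a gross outlier therefore receives the smallest weight."""
    if len(transients) == 1:
        return transients[0].copy()
    mat = np.array([tr.samples for tr in transients])
    med = _median_reference(mat)
    d = np.sum(np.abs(mat - med[None, :]) ** 2, axis=1)
    dmax = d.max()
    if dmax <= 0:  # identical transients -> plain mean
        w = np.full(len(d), 1.0 / len(d))
    else:
        w = 1.0 / np.maximum(d, 1e-12 * dmax) ** 2
        w = w / w.sum()
    avg = np.einsum("i,ij->j", w, mat)
    out = Fid(avg, transients[0].acq, transients[0].label)
    out._weights = w  # stashed for provenance
    return out


def _apply_fp(fid: Fid, df_hz: float, phi_rad: float) -> Fid:
    t = fid.acq.time_axis(len(fid.samples))
    return Fid(
        fid.samples * np.exp(1j * (2 * np.pi * df_hz * t + phi_rad)),
        fid.acq,
        fid.label,
    )


def _region_cost(
    moving: Fid,
    fixed: Fid,
    region: Tuple[float, float],
    edited_shapes: Optional[Sequence[np.ndarray]] = None,
) -> callable:
    """Alignment objective for one sub-spectrum pair.

    The pair difference restricted to the region contains (i) misalignment
    residue of the signals common to both sub-spectra and (ii) the
    genuinely edited difference signal, which no displacement can cancel.
    A plain magnitude minimization is first-order biased by (ii): wings of
    the edited resonances pull the optimum away from the true alignment.
    When ``edited_shapes`` (time-domain model predictions of the edited
    pair-difference signals, amplitudes free) are supplied, their span is
    projected out of the difference and the cost is the squared norm of
    the orthogonal residual -- zero at perfect alignment, hence unbiased
    and idempotent."""
    acq = moving.acq
    n = len(moving.samples)
    nfft = 2 * n
    axis = np.linspace(
        acq.center_ppm + acq.spectral_width / (2 * acq.transmitter_frequency),
        acq.center_ppm - acq.spectral_width / (2 * acq.transmitter_frequency),
        nfft,
    )
    lo, hi = sorted(region)
    sel = (axis >= lo) & (axis <= hi)

    def _spec(samples):
        return np.fft.fftshift(np.fft.fft(samples, n=nfft))[::-1][sel]

    fixed_spec = _spec(fixed.samples)
    Q = None
    if edited_shapes:
        cols = [_spec(s) for s in edited_shapes]
        cols = [c for c in cols if np.linalg.norm(c) > 0]
        if cols:
            Q, _ = np.linalg.qr(np.column_stack(cols))
    t = acq.time_axis(n)

    def cost(x):
        df, phi = x
        s = moving.samples * np.exp(1j * (2 * np.pi * df * t + phi))
        r = _spec(s) - fixed_spec
        c = np.sum(np.abs(r) ** 2)
        if Q is not None:
            c -= np.sum(np.abs(Q.conj().T @ r) ** 2)
        return float(max(c, 0.0))

    return cost


def _align_pair(
    moving: Fid,
    fixed: Fid,
    region: Tuple[float, float],
    edited_shapes: Optional[Sequence[np.ndarray]] = None,
) -> Tuple[Fid, float, float]:
    cost = _region_cost(moving, fixed, region, edited_shapes)
    pb = np.deg2rad(ALIGN_BOUNDS_DEG)
    res = scipy.optimize.minimize(
        cost,
        [0.0, 0.0],
        method="Nelder-Mead",
        bounds=[(-ALIGN_BOUNDS_HZ, ALIGN_BOUNDS_HZ), (-pb, pb)],
        options={
            "initial_simplex": np.array([[0, 0], [0.5, 0], [0, 0.05]]),
            "xatol": 1e-4,
            "fatol": 1e-10,
            "maxiter": 80,
        },
    )
    df, phi = res.x
    return _apply_fp(moving, df, phi), float(df), float(np.rad2deg(phi))


# pairwise alignment order: (moving label, fixed label, region name)
_ALIGN_PAIRS = {
    "HERMES": (("B", "D", "water"), ("C", "D", "tNAA"), ("A", "C", "tCho")),
    "MEGA": (("ON", "OFF", "tNAA"),),
}


# the species whose signal carries the alignment information per region;
# it must never be projected out of the cost, even where (as for the
# residual water) editing also modulates its amplitude
_ALIGN_CARRIER = {"water": "H2O", "tNAA": "NAA", "tCho": "tCho"}


def model_edited_shapes(catalog, acq) -> Dict[str, List[np.ndarray]]:
    """Per alignment pair, the model-predicted edited pair-difference
    signals (time domain, unit concentration): one array per catalog
    species whose response differs between the two sub-experiments.

    These are the signals a perfect alignment can never cancel; the
    alignment objective projects their span out of the pair difference.
    The region's carrier species is kept out of the projection: its
    misalignment residue is the information the alignment runs on.
    """
    from .signal_model import synth_fid  # local to avoid cycle at import

    scheme = "HERMES" if catalog.te_preset == "HERMES80" else "MEGA"
    shapes: Dict[str, List[np.ndarray]] = {}
    for moving, fixed, region_name in _ALIGN_PAIRS[scheme]:
        carrier = _ALIGN_CARRIER[region_name]
        cols = []
        for name, per_label in catalog.entries.items():
            if name == carrier:
                continue
            a = synth_fid([per_label[moving]], {name: 1.0}, acq).samples
            b = synth_fid([per_label[fixed]], {name: 1.0}, acq).samples
            d = a - b
            if np.max(np.abs(d)) > 1e-12:
                cols.append(d)
        shapes[moving] = cols
    return shapes


def align_subspectra(
    averaged: Mapping[str, Fid],
    scheme: str,
    edited_shapes: Optional[Mapping[str, Sequence[np.ndarray]]] = None,
) -> Tuple[Dict[str, Fid], Dict[str, Tuple[float, float]]]:
    """Sequential pairwise frequency/phase alignment of the averaged
    sub-spectra.

    HERMES: minimize residual water to align B to D, the 2-ppm tNAA signal
    to align C to D, then the 3.2-ppm tCho signal to align A to C.
    MEGA-PRESS: minimize the 2-ppm tNAA signal in the difference spectrum
    (ON aligned to OFF).  ``edited_shapes`` (see
    :func:`model_edited_shapes`) removes the first-order bias that the
    genuinely edited signals exert on the minimization.  Returns the
    aligned FIDs and the applied (df_hz, phase_deg) per adjusted label.
    """
    if scheme not in _ALIGN_PAIRS:
        raise ValueError(f"unknown scheme {scheme!r}")
    pairs = _ALIGN_PAIRS[scheme]
    need = {p[0] for p in pairs} | {p[1] for p in pairs}
    if not need.issubset(averaged):
        raise ValueError(f"missing labels: {sorted(need - set(averaged))}")
    adjust: Dict[str, Tuple[float, float]] = {}
    out = {k: v.copy() for k, v in averaged.items()}
    for moving, fixed, region_name in pairs:
        shapes = (edited_shapes or {}).get(moving)
        out[moving], df, ph = _align_pair(
            out[moving], out[fixed], ALIGN_REGIONS[region_name], shapes
        )
        adjust[moving] = (df, ph)
    return out, adjust


def hsvd_filter(
    fid: Fid,
    remove_band_ppm: Tuple[float, float] = (4.4, 5.0),
    rank: int = 25,
    model_points: int = 1024,
) -> Fid:
    """Hankel-SVD decomposition into damped sinusoids; components whose
    frequency falls inside ``remove_band_ppm`` are reconstructed over the
    full FID and subtracted (residual water removal / baseline-roll
    reduction)."""
    n = len(fid.samples)
    m = min(model_points, n)
    if rank >= m / 2:
        raise ValueError("rank must be < model_points/2")
    x = fid.samples[:m]
    L = m // 2
    H = scipy.linalg.hankel(x[:L], x[L - 1 : m])
    U, s, Vh = scipy.linalg.svd(H, full_matrices=False)
    Uk = U[:, :rank]
    # shift-invariance eigenproblem for the signal-subspace poles
    Zp = np.linalg.pinv(Uk[:-1]) @ Uk[1:]
    z = np.linalg.eigvals(Zp)
    if not np.all(np.isfinite(z)):
        raise ValueError("degenerate input: eigenproblem did not converge")
    dt = fid.acq.dwell_time
    # clamp growing poles so full-length reconstruction stays bounded
    mag = np.minimum(np.abs(z), 1.0)
    ang = np.angle(z)
    logz = np.log(np.maximum(mag, 1e-12)) + 1j * ang
    freqs = ang / (2 * np.pi * dt)
    ppm = fid.acq.center_ppm + freqs / fid.acq.transmitter_frequency
    # amplitudes by least squares on the model region
    k_model = np.arange(m)
    V = np.exp(np.outer(k_model, logz))
    c, *_ = np.linalg.lstsq(V, x, rcond=None)
    lo, hi = sorted(remove_band_ppm)
    inband = (ppm >= lo) & (ppm <= hi)
    if not np.any(inband):
        return fid.copy()
    k_full = np.arange(n)
    recon = np.exp(np.outer(k_full, logz[inband])) @ c[inband]
    return Fid(fid.samples - recon, fid.acq, fid.label)


@dataclass
class PreprocessConfig:
    """Options for :func:`preprocess_scan`."""

    do_ecc: bool = True
    fit_window_ms: float = 200.0
    register_iters: int = 2
    do_align: bool = True
    #: project model-predicted edited shapes out of the alignment cost
    align_model_shapes: bool = True
    do_hsvd: bool = True
    hsvd_rank: int = 25
    hsvd_points: int = 1024
    hsvd_band: Tuple[float, float] = (4.4, 5.0)
    zerofill: int = 32768
    lb_hz: float = 3.0
    targets: Optional[Tuple[str, ...]] = None  # default: per sequence


@dataclass
class ProcessedScan:
    """Difference spectra, processed water reference, and provenance."""

    diff_spectra: Dict[str, Spectrum]
    water_spectrum: Spectrum
    provenance: List[dict]
    diff_fids: Dict[str, Fid] = field(default_factory=dict)
    registration: Dict[str, RegistrationResult] = field(default_factory=dict)
    subject_id: str = ""
    scan_id: int = 0
    sequence_tag: str = ""
    truth: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("provenance must be non-empty")
        axes = [sp.ppm_axis for sp in self.diff_spectra.values()]
        for ax in axes[1:]:
            if not np.array_equal(ax, axes[0]):
                raise ValueError("difference spectra must share one ppm axis")


def preprocess_scan(raw: RawScan, cfg: Optional[PreprocessConfig] = None) -> ProcessedScan:
    """Run the full preprocessing chain on one raw scan."""
    cfg = cfg or PreprocessConfig()
    acq = raw.acq
    prov: List[dict] = []
    water = raw.water
    transients = {lab: [f.copy() for f in fids] for lab, fids in raw.transients.items()}

    if cfg.do_ecc:
        ecc = np.exp(-1j * _water_phase(raw.water))
        transients = {
            lab: [Fid(f.samples * ecc, f.acq, f.label) for f in fids]
            for lab, fids in transients.items()
        }
        water = Fid(raw.water.samples * ecc, raw.water.acq, raw.water.label)
        prov.append({"step": "eddy_correct", "reference": "water"})

    averaged: Dict[str, Fid] = {}
    registration: Dict[str, RegistrationResult] = {}
    for lab, fids in transients.items():
        if len(fids) > 1:
            aligned, reg = register_transients(
                fids,
                {"fit_window_ms": cfg.fit_window_ms, "max_iter": cfg.register_iters},
            )
        else:
            aligned, reg = fids, RegistrationResult(np.zeros(1), np.zeros(1))
        avg = weighted_average(aligned)
        reg.weights = getattr(avg, "_weights", np.ones(len(aligned)) / len(aligned))
        registration[lab] = reg
        averaged[lab] = avg
    prov.append(
        {
            "step": "register_transients",
            "fit_window_ms": cfg.fit_window_ms,
            "iterations": cfg.register_iters,
        }
    )
    prov.append({"step": "weighted_average", "rule": "1/d^2 from pointwise median"})

    scheme = "HERMES" if raw.sequence_tag == "HERMES80" else "MEGA"
    if cfg.do_align:
        shapes = (
            model_edited_shapes(default_catalog(raw.sequence_tag), acq)
            if cfg.align_model_shapes
            else None
        )
        averaged, adjust = align_subspectra(averaged, scheme, shapes)
        prov.append({"step": "align_subspectra", "scheme": scheme, "applied": adjust})

    targets = cfg.targets or (("GSH", "GABA") if scheme == "HERMES" else ("GSH",))
    diffs: Dict[str, Fid] = {}
    for tgt in targets:
        if scheme == "HERMES":
            diffs[tgt] = hadamard_combine(averaged, tgt)
        else:
            diffs[tgt] = mega_difference(averaged["ON"], averaged["OFF"])
    prov.append({"step": "combine", "scheme": scheme, "targets": list(targets)})

    if cfg.do_hsvd:
        diffs = {
            tgt: hsvd_filter(f, cfg.hsvd_band, cfg.hsvd_rank, cfg.hsvd_points)
            for tgt, f in diffs.items()
        }
        prov.append(
            {
                "step": "hsvd_filter",
                "band_ppm": list(cfg.hsvd_band),
                "rank": cfg.hsvd_rank,
                "model_points": cfg.hsvd_points,
            }
        )

    spectra = {
        tgt: to_spectrum(f, cfg.zerofill, cfg.lb_hz) for tgt, f in diffs.items()
    }
    water_spec = to_spectrum(water, cfg.zerofill, cfg.lb_hz)
    prov.append({"step": "to_spectrum", "zerofill": cfg.zerofill, "lb_hz": cfg.lb_hz})

    return ProcessedScan(
        diff_spectra=spectra,
        water_spectrum=water_spec,
        provenance=prov,
        diff_fids=diffs,
        registration=registration,
        subject_id=raw.subject_id,
        scan_id=raw.scan_id,
        sequence_tag=raw.sequence_tag,
        truth=dict(raw.truth),
    )
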
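"""Synthetic test-retest cohorts of HERMES-80 and MEGA-120 raw scans.

Editing physics is *encoded*, not simulated: each catalog species stores
per-sub-experiment line tables whose phases flip (or not) with the state
of the two editing pulses.  A species tagged ``gsh`` inverts when the
4.56-ppm pulse is off, so it survives the GSH-targeted Hadamard
combination ``(A - B + C - D)/4`` and cancels in the GABA-targeted one;
``gaba``-tagged species behave conversely; untagged species are identical
across sub-experiments and cancel in both differences.  Residual water is
attenuated asymmetrically by the 4.56-ppm editing pulse so a realistic
water residual survives the difference and HSVD has real work to do.

The co-edited aspartyl multiplet near 2.6 ppm is the deliberate
quantification hazard: at TE = 80 ms its lines carry strongly mixed
phases (the preset commits phases of +40/-65/+120/-150 degrees), while at
TE = 120 ms the multiplet is near-absorptive (all phases within +-15
degrees).  These presets are versioned fixtures chosen to reproduce that
qualitative contrast, not spin physics.

Macromolecule "concentrations" are spectral areas in ppm units (the MM
catalog entries share the exact unit-area Gaussian lineshape of the
parametrized MM basis functions, see :func:`editfit.lcm_fit.mm_multiplet`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .lcm_fit import BasisSet, mm_multiplet
from .signal_model import (
    AcquisitionParams,
    Fid,
    HERMES_LABELS,
    MEGA_LABELS,
    Multiplet,
    SpectralLine,
    hadamard_combine,
    mega_difference,
    synth_fid,
)

__all__ = [
    "MetaboliteCatalog",
    "NoiseConfig",
    "CohortConfig",
    "RawScan",
    "default_catalog",
    "default_acquisitions",
    "simulate_scan",
    "simulate_cohort",
    "make_basis",
    "water_reference_multiplet",
    "DEFAULT_TRUTH_MEANS",
]

# (gaba_on, gsh_on) per sub-experiment label
_EDIT_STATES = {
    "HERMES80": {
        "A": (True, True),
        "B": (True, False),
        "C": (False, True),
        "D": (False, False),
    },
    "MEGA120": {"ON": (None, True), "OFF": (None, False)},
}

# Residual-water attenuation per editing state: the 4.56-ppm GSH pulse
# partially saturates water (factor 0.6); small GABA-state asymmetry
# leaves a weak residual in the GABA difference too.
_WATER_FACTORS = {
    "HERMES80": {"A": 0.6 * 0.99, "B": 1.0 * 0.97, "C": 0.6 * 1.01, "D": 1.0 * 1.03},
    "MEGA120": {"ON": 0.6 * 0.98, "OFF": 1.0 * 1.02},
}

#: Default ground-truth means.  Metabolites in mM-like units; MM species in
#: spectral-area (ppm) units; H2O is the residual-water scale in the
#: water-suppressed sub-spectra and water_ref the unsuppressed reference.
DEFAULT_TRUTH_MEANS: Dict[str, float] = {
    "GSH": 2.0,
    "Asp": 3.0,  # NAA-derived aspartyl moiety, co-edited at 4.56 ppm
    "GABA": 1.5,
    "Glx": 9.0,
    "NAA": 12.0,
    "tCr": 8.0,
    "tCho": 2.4,
    "MM093": 6.0,
    "MM12": 8.0,
    "MM14": 4.0,
    "MM30": 12.0,  # ~45% of the GABA+ 3-ppm area
    "H2O": 45.0,
    "water_ref": 1000.0,
}


def _lines(table) -> tuple:
    return tuple(SpectralLine(p, a, ph) for (p, a, ph) in table)


def _base_species(preset: str) -> List[Tuple[Multiplet, str]]:
    """Base multiplets with their editing behavior tag."""
    # shared, unedited background species (drive the alignment targets)
    common = [
        (Multiplet("NAA", _lines([(2.008, 1.0, 0)]), 300.0, 8.0), "none"),
        (
            Multiplet("tCr", _lines([(3.027, 1.0, 0), (3.913, 0.7, 0)]), 250.0, 8.0),
            "none",
        ),
        (Multiplet("tCho", _lines([(3.185, 2.2, 0)]), 250.0, 8.0), "none"),
        (Multiplet("Glx", _lines([(3.71, 0.15, 0), (3.79, 0.15, 0)]), 250.0, 8.0), "gaba"),
        (Multiplet("H2O", _lines([(4.68, 1.0, 0)]), 60.0, 0.0), "water"),
    ]
    acq_ref = AcquisitionParams()  # MM lineshapes use the default grid
    mm12 = replace(mm_multiplet("MM12", 1.20, acq_ref), name="MM12")
    mm14 = replace(mm_multiplet("MM14", 1.40, acq_ref), name="MM14")
    if preset == "HERMES80":
        gsh = Multiplet("GSH", _lines([(2.95, 0.9, 0)]), 600.0, 22.0)
        # short-TE co-edited aspartyl (two doublets of doublets): wide,
        # oscillatory mixed-phase structure whose upfield lobes reach
        # under the 2.95-ppm GSH peak -- not representable by a few
        # absorptive Gaussians plus a smooth baseline
        asp = Multiplet(
            "Asp",
            _lines(
                [
                    (2.39, 0.30, 40.0),
                    (2.46, 0.45, -95.0),
                    (2.52, 0.50, 150.0),
                    (2.58, 0.50, -65.0),
                    (2.64, 0.50, 120.0),
                    (2.71, 0.50, -150.0),
                    (2.78, 0.40, 80.0),
                    (2.86, 0.30, -120.0),
                ]
            ),
            150.0,
            10.0,
        )
        gaba = Multiplet("GABA", _lines([(3.01, 1.0, 0)]), 600.0, 22.0)
        mm30 = replace(mm_multiplet("MM30", 3.00, acq_ref), name="MM30")
        mm093 = replace(mm_multiplet("MM093", 0.915, acq_ref), name="MM093")
        edited = [
            (gsh, "gsh"),
            (asp, "gsh"),
            (mm12, "gsh"),
            (mm14, "gsh"),
            (gaba, "gaba"),
            (mm30, "gaba"),
            (mm093, "gaba"),
        ]
    elif preset == "MEGA120":
        gsh = Multiplet("GSH", _lines([(2.95, 1.0, 0)]), 600.0, 22.0)
        # long-TE co-edited aspartyl: T2-attenuated, compact and
        # near-absorptive -- straightforward for multi-Gaussian modeling
        asp = Multiplet(
            "Asp",
            _lines(
                [
                    (2.49, 0.17, 10.0),
                    (2.55, 0.19, -8.0),
                    (2.61, 0.22, 5.0),
                    (2.67, 0.19, -12.0),
                    (2.73, 0.17, 8.0),
                ]
            ),
            250.0,
            8.0,
        )
        edited = [(gsh, "gsh"), (asp, "gsh"), (mm12, "gsh"), (mm14, "gsh")]
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return edited + common


def _flip(m: Multiplet) -> Multiplet:
    return replace(
        m,
        lines=tuple(
            SpectralLine(l.offset_ppm, l.amplitude, l.phase_deg + 180.0)
            for l in m.lines
        ),
    )


def _scale(m: Multiplet, factor: float) -> Multiplet:
    return replace(
        m,
        lines=tuple(
            SpectralLine(l.offset_ppm, l.amplitude * factor, l.phase_deg)
            for l in m.lines
        ),
    )


@dataclass
class MetaboliteCatalog:
    """Per-sub-experiment line tables: name -> {label -> Multiplet}."""

    entries: Dict[str, Dict[str, Multiplet]]
    te_preset: str

    @property
    def names(self) -> List[str]:
        return list(self.entries)

    @property
    def labels(self) -> tuple:
        return HERMES_LABELS if self.te_preset == "HERMES80" else MEGA_LABELS

    def multiplets_for(self, label: str) -> List[Multiplet]:
        return [per_label[label] for per_label in self.entries.values()]


def default_catalog(te_preset: str) -> MetaboliteCatalog:
    """Build the committed catalog for a TE preset (HERMES80 | MEGA120)."""
    if te_preset not in _EDIT_STATES:
        raise ValueError(f"unknown preset {te_preset!r}")
    states = _EDIT_STATES[te_preset]
    wfac = _WATER_FACTORS[te_preset]
    entries: Dict[str, Dict[str, Multiplet]] = {}
    for m, behavior in _base_species(te_preset):
        per_label: Dict[str, Multiplet] = {}
        for label, (gaba_on, gsh_on) in states.items():
            mm = m
            if behavior == "gsh" and not gsh_on:
                mm = _flip(mm)
            elif behavior == "gaba" and gaba_on is False:
                mm = _flip(mm)
            elif behavior == "water":
                mm = _scale(mm, wfac[label])
            per_label[label] = mm
        entries[m.name] = per_label
    return MetaboliteCatalog(entries, te_preset)


def water_reference_multiplet() -> Multiplet:
    """Unsuppressed water resonance used for the reference scan and the
    water basis function."""
    return Multiplet("water_ref", _lines([(4.68, 1.0, 0)]), 60.0, 0.0)


def default_acquisitions(
    n_transients_hermes: int = 256, n_transients_mega: int = 256
) -> Dict[str, AcquisitionParams]:
    """Acquisition parameters for the two sequences of the protocol."""
    return {
        "HERMES80": AcquisitionParams(
            te=80.0,
            sequence_tag="HERMES80",
            editing_frequencies=(1.9, 4.56),
            n_transients=n_transients_hermes,
        ),
        "MEGA120": AcquisitionParams(
            te=120.0,
            sequence_tag="MEGA120",
            editing_frequencies=(4.56,),
            n_transients=n_transients_mega,
        ),
    }


@dataclass
class NoiseConfig:
    """Instrumental instabilities applied to each transient.

    All fields are non-negative; zeroing everything yields identical
    transients.  The eddy-current term multiplies *all* FIDs of a scan
    (including water) by ``exp(i amp e^{-t/tau})`` so the water-based
    correction can invert it.
    """

    noise_sd: float = 6.0  # complex white noise SD per transient point
    drift_hz_per_transient: float = 0.05
    jitter_hz_sd: float = 0.3
    phase_jitter_deg_sd: float = 2.0
    baseline_wobble: float = 1.0  # slow additive baseline distortion
    eddy_phase_amp_rad: float = 0.3
    eddy_tau_ms: float = 60.0

    def __post_init__(self) -> None:
        for f in (
            "noise_sd",
            "drift_hz_per_transient",
            "jitter_hz_sd",
            "phase_jitter_deg_sd",
            "baseline_wobble",
            "eddy_phase_amp_rad",
            "eddy_tau_ms",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


@dataclass
class CohortConfig:
    """Test-retest cohort layout and biological variability."""

    n_subjects: int = 12
    n_scans: int = 2
    truth_means: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUTH_MEANS)
    )
    between_subject_cv: float = 0.10
    within_subject_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.between_subject_cv < 0 or self.within_subject_cv < 0:
            raise ValueError("CVs must be >= 0")
        if self.n_scans < 2:
            raise ValueError("test-retest statistics require n_scans >= 2")


@dataclass
class RawScan:
    """One simulated acquisition: per-sub-experiment transients, matched
    unsuppressed-water FID, and (for synthetic data) the ground truth."""

    transients: Dict[str, List[Fid]]
    water: Fid
    truth: Dict[str, float]
    subject_id: str
    scan_id: int
    sequence_tag: str
    acq: AcquisitionParams = None

    @property
    def labels(self) -> List[str]:
        return list(self.transients)


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def _wobble_fid(rng: np.random.Generator, amp: float, acq: AcquisitionParams) -> np.ndarray:
    """Broad, fast-decaying random components emulating baseline roll."""
    t = acq.time_axis()
    out = np.zeros(acq.n_points, dtype=complex)
    for _ in range(3):
        p = rng.uniform(1.0, 4.2)
        ph = rng.uniform(0, 2 * np.pi)
        a = amp * abs(rng.normal())
        f = (p - acq.center_ppm) * acq.transmitter_frequency
        out += a * np.exp(1j * (ph + 2 * np.pi * f * t)) * np.exp(-t / 0.008)
    return out


def simulate_scan(
    truth: Mapping[str, float],
    acq: AcquisitionParams,
    catalog: MetaboliteCatalog,
    noise: NoiseConfig,
    seed,
    subject_id: str = "S01",
    scan_id: int = 1,
) -> RawScan:
    """Simulate one raw acquisition (all sub-experiment transients plus the
    matched water reference) with known truth.  Deterministic given seed.

    Transients are generated interleaved across sub-experiments (the
    acquisition order of the sequence), so linear frequency drift spreads
    over all sub-spectra.
    """
    rng = np.random.default_rng(seed)
    labels = list(catalog.labels)
    n_sub = len(labels)
    n_per = acq.n_transients // n_sub
    if n_per < 1:
        raise ValueError("n_transients smaller than number of sub-experiments")
    missing = [n for n in catalog.names if n not in truth]
    if missing:
        raise KeyError(f"truth missing entries for {missing}")
    t = acq.time_axis()
    eddy = np.exp(
        1j * noise.eddy_phase_amp_rad * np.exp(-t / (noise.eddy_tau_ms / 1000.0))
    )

    bases = {}
    for lab in labels:
        base = synth_fid(catalog.multiplets_for(lab), truth, acq, label=lab).samples
        base = base + _wobble_fid(rng, noise.baseline_wobble, acq)
        bases[lab] = base * eddy

    n_tot = n_sub * n_per
    centered = np.arange(n_tot) - (n_tot - 1) / 2.0
    drift = noise.drift_hz_per_transient * centered
    jitter = rng.normal(0.0, noise.jitter_hz_sd or 0.0, size=n_tot)
    phases = np.deg2rad(rng.normal(0.0, noise.phase_jitter_deg_sd or 0.0, size=n_tot))
    noise_re = rng.normal(0.0, 1.0, size=(n_tot, acq.n_points))
    noise_im = rng.normal(0.0, 1.0, size=(n_tot, acq.n_points))

    transients: Dict[str, List[Fid]] = {lab: [] for lab in labels}
    for j in range(n_per):
        for s, lab in enumerate(labels):
            g = j * n_sub + s
            mod = np.exp(1j * (2 * np.pi * (drift[g] + jitter[g]) * t + phases[g]))
            samples = bases[lab] * mod + noise.noise_sd * (
                noise_re[g] + 1j * noise_im[g]
            )
            transients[lab].append(Fid(samples, acq, lab))

    wmult = water_reference_multiplet()
    wsamples = (
        synth_fid([wmult], {"water_ref": truth.get("water_ref", 1.0)}, acq).samples
        * eddy
    )
    wsamples = wsamples + noise.noise_sd * (
        rng.normal(0.0, 1.0, acq.n_points) + 1j * rng.normal(0.0, 1.0, acq.n_points)
    )
    water = Fid(wsamples, acq, "WATER")
    return RawScan(
        transients=transients,
        water=water,
        truth=dict(truth),
        subject_id=subject_id,
        scan_id=scan_id,
        sequence_tag=acq.sequence_tag,
        acq=acq,
    )


def draw_cohort_truth(cfg: CohortConfig) -> List[List[Dict[str, float]]]:
    """Subject- and scan-level true concentrations.

    Subject levels are log-normal around ``truth_means`` with
    ``between_subject_cv`` (CV = SD/mean of the log-normal, mean
    preserved); scan levels jitter metabolites (not the water reference)
    with ``within_subject_cv``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(cfg.seed, 901)))
    sb = _lognormal_sigma(cfg.between_subject_cv)
    sw = _lognormal_sigma(cfg.within_subject_cv)
    names = list(cfg.truth_means)
    out = []
    for _ in range(cfg.n_subjects):
        subj = {
            n: cfg.truth_means[n] * np.exp(rng.normal(0.0, sb) - 0.5 * sb**2)
            for n in names
        }
        scans = []
        for _ in range(cfg.n_scans):
            scan = {}
            for n in names:
                if n == "water_ref":
                    scan[n] = subj[n]
                else:
                    scan[n] = subj[n] * np.exp(rng.normal(0.0, sw) - 0.5 * sw**2)
            scans.append(scan)
        out.append(scans)
    return out


def simulate_cohort(
    cfg: CohortConfig,
    acq_map: Optional[Mapping[str, AcquisitionParams]] = None,
    noise: Optional[NoiseConfig] = None,
) -> List[RawScan]:
    """Generate the full test-retest cohort: both sequences per
    subject-scan session, sharing that session's true concentrations."""
    if cfg.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    acq_map = acq_map or default_acquisitions()
    noise = noise or NoiseConfig()
    catalogs = {tag: default_catalog(tag) for tag in acq_map}
    truths = draw_cohort_truth(cfg)
    scans: List[RawScan] = []
    for i in range(cfg.n_subjects):
        sid = f"S{i + 1:02d}"
        for k in range(cfg.n_scans):
            for q, (tag, acq) in enumerate(acq_map.items()):
                ss = np.random.SeedSequence(entropy=(cfg.seed, i, k, q))
                scans.append(
                    simulate_scan(
                        truths[i][k],
                        acq,
                        catalogs[tag],
                        noise,
                        ss,
                        subject_id=sid,
                        scan_id=k + 1,
                    )
                )
    return scans


def make_basis(
    catalog: MetaboliteCatalog,
    acq: AcquisitionParams,
    target: str = "GSH",
    mismatch: Optional[Mapping[str, float]] = None,
) -> BasisSet:
    """Noiseless unit-concentration difference-spectrum FIDs per species.

    With ``mismatch=None`` the basis is exact (the same forward model that
    generates the data), enabling exact-recovery tests.  ``mismatch`` may
    contain ``t2_scale`` (scales every T2), ``shift_ppm_sd`` and ``seed``
    (randomly displaces line positions) to emulate basis/in-vivo
    discrepancy.  Species that cancel in the requested difference are
    omitted.  MM species are omitted as well: they are modeled by the
    parametrized Gaussian functions added via
    :func:`editfit.lcm_fit.add_mm_basis`.
    """
    mismatch = dict(mismatch or {})
    t2_scale = float(mismatch.get("t2_scale", 1.0))
    shift_sd = float(mismatch.get("shift_ppm_sd", 0.0))
    rng = np.random.default_rng(mismatch.get("seed", 0))
    names: List[str] = []
    fids: List[np.ndarray] = []
    for name, per_label in catalog.entries.items():
        if name.startswith("MM") or name == "H2O":
            continue
        subs = {}
        for lab in catalog.labels:
            m = per_label[lab]
            if t2_scale != 1.0:
                m = replace(m, t2_ms=m.t2_ms * t2_scale)
            subs[lab] = synth_fid([m], {name: 1.0}, acq, label=lab)
        if catalog.te_preset == "HERMES80":
            diff = hadamard_combine(subs, target)
        else:
            if target != "GSH":
                raise ValueError("MEGA120 catalog only provides a GSH difference")
            diff = mega_difference(subs["ON"], subs["OFF"])
        s = diff.samples
        if shift_sd > 0:
            dppm = rng.normal(0.0, shift_sd)
            t = acq.time_axis()
            s = s * np.exp(1j * 2 * np.pi * dppm * acq.transmitter_frequency * t)
        if np.max(np.abs(s)) > 1e-10:
            names.append(name)
            fids.append(s)
    return BasisSet(names, np.array(fids), acq)
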
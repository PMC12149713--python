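"""Synthetic DWI tumor phantoms and patient cohorts with known habitat truth.

Each phantom is a 3-D tumor composed of a small number of physiological
subregions ("habitats") with distinct IVIM parameters — e.g. a well-perfused
rim (high f), a densely cellular core (low f, low D) and a necrotic
compartment (low f, high D).  The multi-b-value signal of every voxel is
simulated with the biexponential forward model and corrupted with Rician
noise, the noise model of magnitude MR images.  Cohorts add per-patient
jitter of habitat composition and parameters, and draw a binary treatment
response (pCR) from a logistic model on the realized habitat volume
fractions, so that the downstream habitat features genuinely carry the
outcome signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ivim import BValueScheme, IVIMParams, paper_scheme, predict_signal

__all__ = [
    "HabitatSpec",
    "PhantomSpec",
    "CohortSpec",
    "DWIPhantom",
    "default_habitats",
    "well_separated_habitats",
    "strong_effect_cohort",
    "simulate_covariates",
    "add_rician_noise",
    "make_phantom",
    "make_cohort",
    "save_phantom_nifti",
    "load_phantom_nifti",
]


@dataclass(frozen=True)
class HabitatSpec:
    """One physiological subregion: a name, its IVIM parameters and its
    target share of the tumor volume."""

    name: str
    ivim_params: IVIMParams
    target_fraction: float

    def __post_init__(self):
        if not 0.0 < self.target_fraction < 1.0:
            raise ValueError("target_fraction must lie in (0, 1)")


def default_habitats(fractions: Sequence[float] = (0.30, 0.35, 0.35)) -> tuple:
    """Three-habitat archetype mirroring the physiology of the habitat map:
    label 1 high-perfusion rim, label 2 dense cellular tissue (low f, low D),
    label 3 necrotic-like tissue (low f, high D).  D and D* in mm^2/s.
    """
    f1, f2, f3 = fractions
    return (
        HabitatSpec("high_perfusion",
                    IVIMParams(S0=100.0, D=1.05e-3, f=0.22, Dstar=30e-3), f1),
        HabitatSpec("high_cellularity",
                    IVIMParams(S0=100.0, D=0.70e-3, f=0.06, Dstar=15e-3), f2),
        HabitatSpec("necrotic",
                    IVIMParams(S0=100.0, D=1.60e-3, f=0.05, Dstar=12e-3), f3),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a single synthetic tumor volume."""

    grid_shape: tuple = (16, 16, 10)
    voxel_volume: float = 8.0  # mm^3 (2 x 2 x 2 mm nominal)
    habitats: tuple = field(default_factory=default_habitats)
    bscheme: BValueScheme = field(default_factory=paper_scheme)
    noise_sigma: float = 2.0   # signal units; SNR 50 at b=0 for S0=100
    geometry: str = "nested_shells"
    seed: int = 0

    def __post_init__(self):
        if len(self.habitats) < 1:
            raise ValueError("at least one habitat is required")
        total = sum(h.target_fraction for h in self.habitats)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("habitat target fractions must sum to 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.geometry not in ("nested_shells", "random_blobs"):
            raise ValueError("geometry must be 'nested_shells' or 'random_blobs'")
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic patient cohort.

    The outcome model is logistic in the realized habitat volume fractions:
    P(pCR) = expit(intercept + sum_k coef_k * fraction_k).  Defaults give a
    cohort prevalence near the 36% of the emulated study, with response
    favoured by the perfused and cellular habitats and disfavoured by the
    necrotic one.
    """

    n_patients: int = 143
    split_fraction_test: float = 0.30
    outcome_intercept: float = -1.7
    outcome_coefficients: tuple = (7.0, 3.5, -7.0)
    fraction_jitter: float = 0.45   # sd of Gaussian jitter on log-fractions
    param_jitter: float = 0.05      # relative sd on per-patient D, f, D*
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 < self.split_fraction_test < 1.0:
            raise ValueError("split_fraction_test must lie in (0, 1)")
        if self.fraction_jitter < 0 or self.param_jitter < 0:
            raise ValueError("jitter scales must be nonnegative")


@dataclass
class DWIPhantom:
    """A simulated tumor: 4-D signal, mask, ground-truth labels/parameters."""

    signal: np.ndarray            # (x, y, z, b)
    mask: np.ndarray              # binary, 3-D
    truth_labels: np.ndarray      # 0 = background, 1..K = habitat
    truth_params: tuple           # HabitatSpec per habitat
    bscheme: BValueScheme
    voxel_volume: float
    outcome: int | None = None    # 1 = pCR, 0 = non-pCR (cohort use)
    patient_id: str | None = None

    @property
    def truth_fractions(self) -> np.ndarray:
        n = int(self.mask.sum())
        counts = np.bincount(self.truth_labels[self.mask.astype(bool)],
                             minlength=len(self.truth_params) + 1)[1:]
        return counts / n


def well_separated_habitats(fractions: Sequence[float] = (0.30, 0.35, 0.35)) -> tuple:
    """Three habitats with widely separated (f, D) signatures, for stability
    studies where cluster recovery should be essentially exact at SNR 50."""
    f1, f2, f3 = fractions
    return (
        HabitatSpec("high_perfusion",
                    IVIMParams(S0=100.0, D=1.00e-3, f=0.32, Dstar=35e-3), f1),
        HabitatSpec("high_cellularity",
                    IVIMParams(S0=100.0, D=0.55e-3, f=0.05, Dstar=15e-3), f2),
        HabitatSpec("necrotic",
                    IVIMParams(S0=100.0, D=2.10e-3, f=0.05, Dstar=12e-3), f3),
    )


def strong_effect_cohort(n_patients: int = 140, seed: int = 0,
                         split_fraction_test: float = 0.30) -> CohortSpec:
    """Cohort preset with a strong habitat-composition effect on outcome
    (oracle discriminability of the generating linear predictor ~0.9 AUC at
    ~36% prevalence)."""
    return CohortSpec(n_patients=n_patients,
                      split_fraction_test=split_fraction_test,
                      outcome_intercept=-2.75,
                      outcome_coefficients=(12.0, 6.0, -12.0), seed=seed)


def simulate_covariates(outcomes, seed: int = 0, cf_logodds: float = 1.2,
                        ihc_logodds: float = 1.5) -> pd.DataFrame:
    """Synthetic binary clinical covariates conditioned on the outcome.

    Emulates the conventional-MRI block (rim enhancement, high T2 signal)
    and the immunohistochemistry block (HR negativity, HER2 positivity) as
    Bernoulli covariates whose log-odds shift by the given amount between
    responders and non-responders.
    """
    y = np.asarray(outcomes).astype(int)
    rng = np.random.default_rng(seed)
    base = {"rim_enhancement": -0.4, "high_t2_signal": -0.8,
            "hr_negative": -0.5, "her2_positive": -0.2}
    shift = {"rim_enhancement": cf_logodds, "high_t2_signal": -cf_logodds,
             "hr_negative": ihc_logodds, "her2_positive": ihc_logodds}
    cols = {}
    for name in base:
        p = 1.0 / (1.0 + np.exp(-(base[name] + shift[name] * y)))
        cols[name] = (rng.random(y.size) < p).astype(int)
    return pd.DataFrame(cols)


def add_rician_noise(signal: np.ndarray, sigma: float,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Corrupt a noise-free magnitude signal with Rician noise.

    Returns sqrt((S + n1)^2 + n2^2) with n1, n2 iid N(0, sigma^2); the output
    is the input for sigma = 0 and deterministic for a given seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    signal = np.asarray(signal, dtype=float)
    if np.any(signal < 0):
        raise ValueError("signal must be nonnegative")
    if sigma == 0:
        return signal.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)


def _largest_remainder_counts(fractions: np.ndarray, n: int) -> np.ndarray:
    """Integer counts summing to n, each within 1 of fraction * n."""
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    counts[order[:short]] += 1
    return counts


def _ellipsoid_radius(grid_shape) -> tuple[np.ndarray, np.ndarray]:
    """Normalized ellipsoidal radius on the grid and the tumor mask r <= 1."""
    axes = [np.arange(s, dtype=float) for s in grid_shape]
    center = [(s - 1) / 2.0 for s in grid_shape]
    semi = [max(s / 2.0 - 0.5, 0.5) for s in grid_shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(((X - center[0]) / semi[0]) ** 2
                + ((Y - center[1]) / semi[1]) ** 2
                + ((Z - center[2]) / semi[2]) ** 2)
    return r, r <= 1.0


def _labels_nested_shells(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    r, mask = _ellipsoid_radius(spec.grid_shape)
    idx = np.nonzero(mask)
    order = np.argsort(r[idx], kind="stable")  # innermost first
    fractions = np.array([h.target_fraction for h in spec.habitats])
    counts = _largest_remainder_counts(fractions, order.size)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    flat = np.repeat(np.arange(1, len(counts) + 1), counts)
    labels[tuple(c[order] for c in idx)] = flat
    return labels, mask.astype(np.uint8)


def _labels_random_blobs(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(spec.seed)
    r, mask = _ellipsoid_radius(spec.grid_shape)
    field_ = gaussian_filter(rng.normal(size=spec.grid_shape), sigma=2.0)
    idx = np.nonzero(mask)
    order = np.argsort(field_[idx], kind="stable")
    fractions = np.array([h.target_fraction for h in spec.habitats])
    counts = _largest_remainder_counts(fractions, order.size)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    flat = np.repeat(np.arange(1, len(counts) + 1), counts)
    labels[tuple(c[order] for c in idx)] = flat
    return labels, mask.astype(np.uint8)


def make_phantom(spec: PhantomSpec,
                 rng: np.random.Generator | None = None) -> DWIPhantom:
    """Build one DWI phantom from its specification.

    Habitat labels are laid out either as concentric ellipsoid shells
    (fraction-exact, deterministic) or as seeded smooth random blobs; every
    tumor voxel's decay curve is the biexponential forward signal of its
    habitat, and Rician noise is applied per b-value image with the effective
    sigma reduced by sqrt(n_averages) where the scheme records averages.
    """
    if spec.geometry == "nested_shells":
        labels, mask = _labels_nested_shells(spec)
    else:
        labels, mask = _labels_random_blobs(spec)

    b = spec.bscheme.b
    signal = np.zeros(spec.grid_shape + (b.size,), dtype=float)
    for k, hab in enumerate(spec.habitats, start=1):
        decay = predict_signal(hab.ivim_params, spec.bscheme)
        signal[labels == k] = decay

    if spec.noise_sigma > 0:
        rng = rng or np.random.default_rng(spec.seed)
        if spec.bscheme.n_averages is not None:
            sig_eff = spec.noise_sigma / np.sqrt(np.asarray(spec.bscheme.n_averages))
        else:
            sig_eff = np.full(b.size, spec.noise_sigma)
        for j in range(b.size):
            signal[..., j] = add_rician_noise(signal[..., j], float(sig_eff[j]), rng)

    return DWIPhantom(signal=signal, mask=mask, truth_labels=labels,
                      truth_params=tuple(spec.habitats), bscheme=spec.bscheme,
                      voxel_volume=spec.voxel_volume)


def _jitter_habitats(habitats, frac_jitter, param_jitter, rng):
    """Per-patient perturbation of habitat composition and IVIM parameters."""
    base = np.array([h.target_fraction for h in habitats])
    logf = np.log(base) + rng.normal(0.0, frac_jitter, base.size)
    frac = np.exp(logf)
    frac /= frac.sum()
    frac = np.clip(frac, 1e-3, None)
    frac /= frac.sum()
    out = []
    for h, fr in zip(habitats, frac):
        p = h.ivim_params
        mult = np.exp(rng.normal(0.0, param_jitter, 3))
        D = p.D * mult[0]
        f = float(np.clip(p.f * mult[1], 0.0, 0.45))
        Dstar = max(p.Dstar * mult[2], D * 1.5)
        out.append(HabitatSpec(h.name, IVIMParams(S0=p.S0, D=D, f=f, Dstar=Dstar), float(fr)))
    return tuple(out)


def make_cohort(pspec: PhantomSpec, cspec: CohortSpec):
    """Simulate a patient cohort of DWI phantoms with outcomes and a split.

    Returns ``(phantoms, manifest)`` where the manifest is a DataFrame with
    patient_id, outcome, split and the realized habitat fractions.  Outcomes
    are Bernoulli draws from the logistic model on realized volume fractions;
    the train/test split is a seeded shuffle.
    """
    if len(cspec.outcome_coefficients) != len(pspec.habitats):
        raise ValueError("need one outcome coefficient per habitat")
    rng = np.random.default_rng(cspec.seed)
    phantoms, rows = [], []
    for i in range(cspec.n_patients):
        habs = _jitter_habitats(pspec.habitats, cspec.fraction_jitter,
                                cspec.param_jitter, rng)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec_i = PhantomSpec(grid_shape=pspec.grid_shape,
                             voxel_volume=pspec.voxel_volume, habitats=habs,
                             bscheme=pspec.bscheme, noise_sigma=pspec.noise_sigma,
                             geometry=pspec.geometry, seed=sub_seed)
        ph = make_phantom(spec_i, rng=np.random.default_rng(sub_seed))
        frac = ph.truth_fractions
        eta = cspec.outcome_intercept + float(np.dot(cspec.outcome_coefficients, frac))
        p = 1.0 / (1.0 + np.exp(-eta))
        outcome = int(rng.random() < p)
        ph.outcome = outcome
        ph.patient_id = f"P{i:04d}"
        phantoms.append(ph)
        rows.append({"patient_id": ph.patient_id, "outcome": outcome,
                     **{f"truth_frac_{k+1}": frac[k] for k in range(frac.size)}})

    n_test = int(round(cspec.n_patients * cspec.split_fraction_test))
    perm = rng.permutation(cspec.n_patients)
    split = np.array(["train"] * cspec.n_patients, dtype=object)
    split[perm[:n_test]] = "test"
    manifest = pd.DataFrame(rows)
    manifest["split"] = split
    return phantoms, manifest


# ---------------------------------------------------------------------------
# NIfTI round-trip


def save_phantom_nifti(phantom: DWIPhantom, outdir) -> dict:
    """Write signal (4-D), mask and truth labels as .nii.gz plus a JSON sidecar
    with b-values and habitat parameters; returns the path map."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    paths = {
        "signal": outdir / "dwi.nii.gz",
        "mask": outdir / "mask.nii.gz",
        "labels": outdir / "truth_labels.nii.gz",
        "sidecar": outdir / "phantom.json",
    }
    nib.save(nib.Nifti1Image(phantom.signal.astype(np.float32), affine), paths["signal"])
    nib.save(nib.Nifti1Image(phantom.mask.astype(np.uint8), affine), paths["mask"])
    nib.save(nib.Nifti1Image(phantom.truth_labels.astype(np.int16), affine), paths["labels"])
    sidecar = {
        "bvalues": list(phantom.bscheme.bvalues),
        "n_averages": list(phantom.bscheme.n_averages) if phantom.bscheme.n_averages else None,
        "voxel_volume": phantom.voxel_volume,
        "outcome": phantom.outcome,
        "patient_id": phantom.patient_id,
        "habitats": [
            {"name": h.name, "target_fraction": h.target_fraction,
             "S0": h.ivim_params.S0, "D": h.ivim_params.D,
             "f": h.ivim_params.f, "Dstar": h.ivim_params.Dstar}
            for h in phantom.truth_params
        ],
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=1))
    return {k: str(v) for k, v in paths.items()}


def load_phantom_nifti(outdir) -> DWIPhantom:
    import nibabel as nib

    outdir = Path(outdir)
    sidecar = json.loads((outdir / "phantom.json").read_text())
    bscheme = BValueScheme(tuple(sidecar["bvalues"]),
                           tuple(sidecar["n_averages"]) if sidecar["n_averages"] else None)
    habs = tuple(
        HabitatSpec(h["name"],
                    IVIMParams(S0=h["S0"], D=h["D"], f=h["f"], Dstar=h["Dstar"]),
                    h["target_fraction"])
        for h in sidecar["habitats"]
    )
    return DWIPhantom(
        signal=np.asarray(nib.load(outdir / "dwi.nii.gz").dataobj, dtype=np.float32).astype(float),
        mask=np.asarray(nib.load(outdir / "mask.nii.gz").dataobj).astype(np.uint8),
        truth_labels=np.asarray(nib.load(outdir / "truth_labels.nii.gz").dataobj).astype(np.int16),
        truth_params=habs, bscheme=bscheme,
        voxel_volume=float(sidecar["voxel_volume"]),
        outcome=sidecar["outcome"], patient_id=sidecar["patient_id"],
    )
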
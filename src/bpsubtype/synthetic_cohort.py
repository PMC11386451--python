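"""Synthetic MSI/MSS histology cohorts with genomically-coupled morphology.

This module simulates the study material for the class-decomposition
experiments: a cohort of colorectal-cancer patients, each carrying a
molecular subtype (MSI or MSS), patient-level genomic covariates (SNP
count, CIMP methylation category, CNV fraction) and a set of small RGB
"patch" images whose texture statistics encode both the subtype and a
hidden morphological mode.

The central knob is the *fidelity* rho of each genomic feature: the
strength of coupling between a patient's covariate and the morphological
mode of their patches.  At rho=1 the mode is readable off the covariate
(high-SNP patients look one way, low-SNP patients another); at rho=0 the
covariate is independent of morphology.  Decomposing the MSI class by a
covariate during training can therefore only help when rho > 0 — which
is precisely the effect the downstream experiments measure.

Morphology is a parametric proxy for H&E appearance: randomly placed
elliptical "nuclei" on a textured background, with per-(subtype, mode)
nucleus density, size, pleomorphism (size variance), eccentricity and
stain hue.  MSS has a single phenotype; the two MSI modes bracket it in
nucleus density and size, so a binary classifier must learn a
non-convex MSI region while a three-class model sees each mode as its
own target.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from PIL import Image
from scipy.stats import norm

__all__ = [
    "LogNormalSpec",
    "BetaSpec",
    "GeneratorConfig",
    "PatientRecord",
    "PatchRecord",
    "generate_cohort",
    "draw_patients",
    "render_patch",
    "write_manifests",
    "read_manifests",
    "write_images",
    "load_image",
]

Subtype = Literal["MSI", "MSS"]
Split = Literal["train", "test"]


# ---------------------------------------------------------------------------
# distribution specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogNormalSpec:
    """Truncated log-normal, calibrated so the *truncated* median equals
    ``median`` exactly (the location parameter is solved by fixed-point
    iteration; truncation would otherwise shift the median slightly)."""

    median: float
    sigma: float
    lo: float
    hi: float

    def _mu(self) -> float:
        mu = math.log(self.median)
        for _ in range(8):
            a = norm.cdf((math.log(self.lo) - mu) / self.sigma)
            b = norm.cdf((math.log(self.hi) - mu) / self.sigma)
            mu = math.log(self.median) - self.sigma * norm.ppf((a + b) / 2.0)
        return mu

    def ppf(self, q):
        """Quantile function of the truncated distribution, q in [0, 1)."""
        mu = self._mu()
        a = norm.cdf((math.log(self.lo) - mu) / self.sigma)
        b = norm.cdf((math.log(self.hi) - mu) / self.sigma)
        return np.exp(mu + self.sigma * norm.ppf(a + np.asarray(q) * (b - a)))

    def sample(self, rng: np.random.Generator, n: int | None = None):
        u = rng.random(n) if n is not None else rng.random()
        return self.ppf(u)


@dataclass(frozen=True)
class BetaSpec:
    a: float
    b: float

    def sample(self, rng: np.random.Generator, n: int | None = None):
        return rng.beta(self.a, self.b, n)


# ---------------------------------------------------------------------------
# configuration and records
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Cohort-level simulation parameters.

    Defaults reproduce the study conditions: 260 training / 100 test
    patients, MSI prevalence 15% (train) and 26% (test), MSI SNP counts
    on a heavy-tailed distribution with median 1432 truncated to
    [10, 17000], CIMP-H in 60% of MSI and 5%/1% of MSS train/test, CNV
    low in MSI (concentrated near the 0.005 decision point) and elevated
    with wide spread in MSS.
    """

    n_train_patients: int = 260
    n_test_patients: int = 100
    msi_fraction_train: float = 0.15
    msi_fraction_test: float = 0.26
    patches_per_patient: int | tuple[int, int] = 20
    image_size: int = 64
    snp_msi_dist: LogNormalSpec = field(
        default_factory=lambda: LogNormalSpec(median=1432.0, sigma=1.1, lo=10.0, hi=17000.0)
    )
    snp_mss_dist: LogNormalSpec = field(
        default_factory=lambda: LogNormalSpec(median=60.0, sigma=0.8, lo=1.0, hi=500.0)
    )
    cimp_h_fraction_msi: float = 0.60
    cimp_h_fraction_mss_train: float = 0.05
    cimp_h_fraction_mss_test: float = 0.01
    cnv_msi_dist: LogNormalSpec = field(
        default_factory=lambda: LogNormalSpec(median=0.003, sigma=0.8, lo=1e-4, hi=0.05)
    )
    cnv_mss_dist: BetaSpec = field(default_factory=lambda: BetaSpec(a=2.5, b=5.0))
    patient_jitter_lam: float = 0.30   # log-sd of per-patient nucleus-count multiplier
    patient_jitter_r: float = 0.15     # log-sd of per-patient radius multiplier
    patient_jitter_bg: float = 2.0     # per-channel sd of per-patient background shift
    patient_jitter_nuc: float = 5.0    # per-channel sd of per-patient nucleus stain shift
    fidelity_snp: float = 1.0
    fidelity_cimp: float = 1.0
    fidelity_cnv: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "msi_fraction_train",
            "msi_fraction_test",
            "cimp_h_fraction_msi",
            "cimp_h_fraction_mss_train",
            "cimp_h_fraction_mss_test",
            "fidelity_snp",
            "fidelity_cimp",
            "fidelity_cnv",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.n_train_patients <= 0 or self.n_test_patients <= 0:
            raise ValueError("patient counts must be positive")
        lo, hi = self._patch_range()
        if lo <= 0:
            raise ValueError("patches_per_patient must be positive")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")

    def _patch_range(self) -> tuple[int, int]:
        p = self.patches_per_patient
        if isinstance(p, tuple):
            return int(p[0]), int(p[1])
        return int(p), int(p)


@dataclass
class PatientRecord:
    patient_id: str
    split: Split
    subtype: Subtype
    snp_count: int
    cimp_category: str  # CIMP-H | CIMP-L | non-CIMP
    cnv_fraction: float
    latent_mode: str  # A | B
    n_patches: int


@dataclass
class PatchRecord:
    patch_id: str
    patient_id: str
    image_ref: str
    base_label: Subtype
    sub_label: str | None = None


# ---------------------------------------------------------------------------
# patch renderer
# ---------------------------------------------------------------------------

# Per-(subtype, mode) morphology.  The two MSI modes carry orthogonal
# signatures: mode A matches MSS in nucleus density and size but has
# hematoxylin-shifted (bluer, denser-chromatin) nuclei; mode B matches the
# MSS stain but has many large, pleomorphic nuclei.  A binary classifier
# must pool two unrelated detectors into one score, while a three-class
# model dedicates a boundary to each mode.
PHENOTYPES: dict[tuple[str, str | None], dict] = {
    ("MSS", None): dict(
        lam=32.0, r_mean=3.0, r_sd=0.45, ecc=0.25,
        base=(224.0, 198.0, 216.0), nuc=(115.0, 87.0, 152.0),
    ),
    ("MSI", "A"): dict(
        lam=32.0, r_mean=3.0, r_sd=0.45, ecc=0.45,
        base=(224.0, 198.0, 216.0), nuc=(123.0, 83.0, 160.0),
    ),
    ("MSI", "B"): dict(
        lam=58.0, r_mean=4.6, r_sd=1.30, ecc=0.25,
        base=(224.0, 198.0, 216.0), nuc=(115.0, 87.0, 152.0),
    ),
}

_BG_NOISE_SD = 7.0
_NUC_COLOR_JITTER = 8.0


def render_patch(
    subtype: Subtype,
    mode: str | None,
    size: int,
    rng: np.random.Generator,
    jitter: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Render one synthetic H&E-like patch as an (size, size, 3) uint8 array.

    MSS has a single phenotype: ``mode`` is ignored for MSS patches.
    ``jitter`` carries optional patient-level appearance multipliers
    (``lam_mult``, ``r_mult``) and a scalar background ``brightness``
    shift, emulating slide-to-slide staining and morphology variability;
    it is identical for every patch of one patient and independent of
    subtype, so it adds patient-level noise without leaking the label.
    Identical RNG state and arguments yield an identical image.
    """
    if size < 32:
        raise ValueError(f"patch size must be >= 32, got {size}")
    key = (subtype, None if subtype == "MSS" else mode)
    if key not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {subtype!r}/{mode!r}")
    p = PHENOTYPES[key]
    j = {"lam_mult": 1.0, "r_mult": 1.0, "bg_shift": 0.0, "nuc_shift": 0.0}
    if jitter:
        j.update(jitter)

    img = np.empty((size, size, 3), dtype=np.float64)
    img[:] = np.asarray(p["base"]) + np.asarray(j["bg_shift"])
    img += rng.normal(0.0, _BG_NOISE_SD, size=(size, size, 3))

    scale = (size / 64.0) ** 2
    n_nuclei = rng.poisson(p["lam"] * j["lam_mult"] * scale)
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, size, size=2)
        r = max(rng.normal(p["r_mean"], p["r_sd"]) * j["r_mult"], 1.2)
        ratio = 1.0 + rng.exponential(p["ecc"])
        ry, rx = r * math.sqrt(ratio), r / math.sqrt(ratio)
        theta = rng.uniform(0.0, math.pi)
        color = np.asarray(p["nuc"]) + np.asarray(j["nuc_shift"]) + rng.normal(
            0.0, _NUC_COLOR_JITTER, size=3
        )
        ct, st = math.cos(theta), math.sin(theta)
        # bounding box to keep the mask cheap
        rmax = max(ry, rx)
        y0, y1 = max(int(cy - rmax - 1), 0), min(int(cy + rmax + 2), size)
        x0, x1 = max(int(cx - rmax - 1), 0), min(int(cx + rmax + 2), size)
        if y0 >= y1 or x0 >= x1:
            continue
        dy = yy[y0:y1, x0:x1] - cy
        dx = xx[y0:y1, x0:x1] - cx
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        mask = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
        region = img[y0:y1, x0:x1]
        region[mask] = 0.25 * region[mask] + 0.75 * color

    return np.clip(img, 0.0, 255.0).astype(np.uint8)


# ---------------------------------------------------------------------------
# patient-level covariate simulation
# ---------------------------------------------------------------------------


def _draw_side_conditional(
    dist: LogNormalSpec, mode_is_high: bool, rho: float, rng: np.random.Generator
) -> float:
    """Draw from ``dist`` on the side of its median matching the latent mode
    with probability (1+rho)/2 (opposite side otherwise).  Because the two
    sides are sampled with equal probability overall, the marginal
    distribution is exactly ``dist`` for every rho."""
    agree = rng.random() < (1.0 + rho) / 2.0
    high = mode_is_high if agree else not mode_is_high
    u = rng.random()
    q = 0.5 + 0.5 * u if high else 0.5 * u
    return float(dist.ppf(q))


def _draw_cimp_msi(mode_is_high: bool, base_h: float, rho: float, rng: np.random.Generator) -> str:
    # Conditional CIMP-H rates chosen so the marginal stays at base_h for
    # every rho (modes are 50/50): P(H|B) = h + (1-h)rho', P(H|A) = h - (1-h)rho'
    # with rho' scaled by (1-h) to keep probabilities in [0,1] at rho=1.
    delta = (1.0 - base_h) * rho
    p_h = base_h + delta if mode_is_high else base_h - delta
    if rng.random() < p_h:
        return "CIMP-H"
    return "CIMP-L" if rng.random() < 0.5 else "non-CIMP"


def draw_patients(
    config: GeneratorConfig,
    n: int,
    subtype: Subtype,
    split: Split,
    rng: np.random.Generator,
    id_prefix: str = "P",
) -> list[PatientRecord]:
    """Draw ``n`` patients of one subtype with covariates and latent modes."""
    lo, hi = config._patch_range()
    mss_h = (
        config.cimp_h_fraction_mss_train if split == "train" else config.cimp_h_fraction_mss_test
    )
    out: list[PatientRecord] = []
    for i in range(n):
        pid = f"{id_prefix}{i:05d}"
        n_patches = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        if subtype == "MSI":
            mode_high = bool(rng.random() < 0.5)  # mode B = "high" morphology
            snp = _draw_side_conditional(config.snp_msi_dist, mode_high, config.fidelity_snp, rng)
            cimp = _draw_cimp_msi(mode_high, config.cimp_h_fraction_msi, config.fidelity_cimp, rng)
            cnv = _draw_side_conditional(config.cnv_msi_dist, mode_high, config.fidelity_cnv, rng)
            mode = "B" if mode_high else "A"
        else:
            snp = config.snp_mss_dist.sample(rng)
            u = rng.random()
            cimp = "CIMP-H" if u < mss_h else ("CIMP-L" if rng.random() < 0.25 else "non-CIMP")
            cnv = float(config.cnv_mss_dist.sample(rng))
            mode = "A"
        out.append(
            PatientRecord(
                patient_id=pid,
                split=split,
                subtype=subtype,
                snp_count=int(round(snp)),
                cimp_category=cimp,
                cnv_fraction=float(np.clip(cnv, 0.0, 1.0)),
                latent_mode=mode,
                n_patches=n_patches,
            )
        )
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _split_cohort(
    config: GeneratorConfig, split: Split, rng: np.random.Generator
) -> list[PatientRecord]:
    n = config.n_train_patients if split == "train" else config.n_test_patients
    frac = config.msi_fraction_train if split == "train" else config.msi_fraction_test
    n_msi = int(round(n * frac))
    n_mss = n - n_msi
    if n_msi == 0 or n_mss == 0:
        raise ValueError(
            f"{split} split would contain zero patients of one class "
            f"(n={n}, msi_fraction={frac})"
        )
    prefix = "TR" if split == "train" else "TE"
    msi = draw_patients(config, n_msi, "MSI", split, rng, id_prefix=f"{prefix}I")
    mss = draw_patients(config, n_mss, "MSS", split, rng, id_prefix=f"{prefix}S")
    patients = msi + mss
    order = rng.permutation(len(patients))
    return [patients[i] for i in order]


def generate_cohort(
    config: GeneratorConfig,
    out_dir: str | os.PathLike | None = None,
    render: bool = True,
) -> tuple[list[PatientRecord], list[PatchRecord], dict[str, np.ndarray]]:
    """Generate a full cohort: patients, patch records, and patch images.

    Returns ``(patients, patches, images)`` where ``images`` maps
    patch_id -> uint8 RGB array.  When ``out_dir`` is given, PNGs and the
    two manifest CSVs are also written there and each patch's
    ``image_ref`` is its PNG path; otherwise ``image_ref`` is a
    ``mem://`` key into the returned store.  With ``render=False`` only
    the records are produced (covariate-level studies).

    Generation is bitwise reproducible for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients = _split_cohort(config, "train", rng) + _split_cohort(config, "test", rng)

    patches: list[PatchRecord] = []
    images: dict[str, np.ndarray] = {}
    for pat in patients:
        jitter = {
            "lam_mult": float(np.exp(rng.normal(0.0, config.patient_jitter_lam))),
            "r_mult": float(np.exp(rng.normal(0.0, config.patient_jitter_r))),
            "bg_shift": rng.normal(0.0, config.patient_jitter_bg, size=3),
            "nuc_shift": rng.normal(0.0, config.patient_jitter_nuc, size=3),
        }
        for j in range(pat.n_patches):
            patch_id = f"{pat.patient_id}_p{j:03d}"
            ref = f"mem://{patch_id}"
            patches.append(
                PatchRecord(
                    patch_id=patch_id,
                    patient_id=pat.patient_id,
                    image_ref=ref,
                    base_label=pat.subtype,
                )
            )
            if render:
                images[patch_id] = render_patch(
                    pat.subtype, pat.latent_mode, config.image_size, rng, jitter
                )

    if out_dir is not None:
        out_dir = Path(out_dir)
        if render:
            refs = write_images(images, out_dir)
            for rec in patches:
                rec.image_ref = refs[rec.patch_id]
        write_manifests(patients, patches, out_dir)
    return patients, patches, images


# ---------------------------------------------------------------------------
# manifests and image I/O
# ---------------------------------------------------------------------------

PATIENT_COLUMNS = [
    "patient_id", "split", "subtype", "snp_count",
    "cimp_category", "cnv_fraction", "latent_mode", "n_patches",
]
PATCH_COLUMNS = ["patch_id", "patient_id", "image_path"]


def write_manifests(
    patients: list[PatientRecord],
    patches: list[PatchRecord],
    out_dir: str | os.PathLike,
) -> tuple[Path, Path]:
    """Write patients.csv and patches.csv with stable column order."""
    if not patches:
        raise ValueError("patch list is empty")
    if not patients:
        raise ValueError("patient list is empty")
    known = {p.patient_id for p in patients}
    orphans = sorted({q.patient_id for q in patches} - known)
    if orphans:
        raise ValueError(f"patches reference unknown patients: {orphans[:5]}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValueError(f"cannot create output directory {out_dir}: {exc}") from exc
    pat_df = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id, "split": p.split, "subtype": p.subtype,
                "snp_count": p.snp_count, "cimp_category": p.cimp_category,
                "cnv_fraction": p.cnv_fraction, "latent_mode": p.latent_mode,
                "n_patches": p.n_patches,
            }
            for p in patients
        ],
        columns=PATIENT_COLUMNS,
    )
    patch_df = pd.DataFrame(
        [
            {"patch_id": q.patch_id, "patient_id": q.patient_id, "image_path": q.image_ref}
            for q in patches
        ],
        columns=PATCH_COLUMNS,
    )
    p_path = out_dir / "patients.csv"
    q_path = out_dir / "patches.csv"
    pat_df.to_csv(p_path, index=False)
    patch_df.to_csv(q_path, index=False)
    return p_path, q_path


def read_manifests(
    in_dir: str | os.PathLike,
) -> tuple[list[PatientRecord], list[PatchRecord]]:
    in_dir = Path(in_dir)
    pat_df = pd.read_csv(in_dir / "patients.csv")
    patch_df = pd.read_csv(in_dir / "patches.csv")
    patients = [
        PatientRecord(
            patient_id=str(r.patient_id), split=r.split, subtype=r.subtype,
            snp_count=int(r.snp_count), cimp_category=r.cimp_category,
            cnv_fraction=float(r.cnv_fraction), latent_mode=r.latent_mode,
            n_patches=int(r.n_patches),
        )
        for r in pat_df.itertuples()
    ]
    by_id = {p.patient_id: p for p in patients}
    patches = [
        PatchRecord(
            patch_id=str(r.patch_id), patient_id=str(r.patient_id),
            image_ref=str(r.image_path),
            base_label=by_id[str(r.patient_id)].subtype,
        )
        for r in patch_df.itertuples()
    ]
    return patients, patches


def write_images(images: dict[str, np.ndarray], out_dir: str | os.PathLike) -> dict[str, str]:
    """Write each patch image as PNG under ``out_dir/images``; returns
    patch_id -> path written."""
    img_dir = Path(out_dir) / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    refs: dict[str, str] = {}
    for patch_id, arr in images.items():
        path = img_dir / f"{patch_id}.png"
        Image.fromarray(arr, mode="RGB").save(path)
        refs[patch_id] = str(path)
    return refs


def load_image(image_ref: str, images: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Resolve an image_ref: either a mem:// key into ``images`` or a path."""
    if image_ref.startswith("mem://"):
        key = image_ref[len("mem://"):]
        if images is None or key not in images:
            raise FileNotFoundError(f"in-memory image {image_ref} not available")
        return images[key]
    if not os.path.exists(image_ref):
        raise FileNotFoundError(f"image file not found: {image_ref}")
    return np.asarray(Image.open(image_ref).convert("RGB"))
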
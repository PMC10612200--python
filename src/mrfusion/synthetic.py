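"""Synthetic multi-sequence phantom cohorts and feature tables.

No imaging data accompany the study this package operationalizes, so the
generator emulates the statistical structure the models assume: three
co-registered channels (T2w, T1c, ADC) in which the class signal is
distributed unevenly.  Each phantom patient is an elliptical lesion on
Gaussian background noise; in a poor responder the lesion's channel-c
mean intensity is shifted by ``effect[c]`` noise-SD units and its internal
texture is coarsened (correlation length of smoothed noise grows with
``effect[c]``), so both first-order and texture features carry signal.
Clinical covariates are drawn independently of the label by default,
mirroring the clinical finding that none of them was predictive.

The default cohort composition mirrors the two hospital cohorts: a
267-patient development cohort with 147 poor responders (55.1%, split
193 train / 74 internal validation) and a 155-patient external cohort
with 112 poor responders (72.3%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io_formats import (
    AnnotatedSlice,
    ClinicalRecord,
    MultiSequencePatch,
    PATCH_SIZE,
    SEQUENCES,
    crop_patch,
    save_slice_nifti,
    write_clinical_table,
)
from .radiomics import FeatureMatrix, canonical_feature_names

# printed cohort composition of the two hospitals
SAHSYU_N, SAHSYU_POOR = 267, 147
ZCH_N, ZCH_POOR = 155, 112
TRAIN_N, INTERNAL_N = 193, 74
TOTAL_N = SAHSYU_N + ZCH_N  # 422


@dataclass
class PhantomSpec:
    """Generation parameters for one phantom image cohort.

    ``effect`` is the per-channel (T2w, T1c, ADC) class effect in noise-SD
    units; it shifts the lesion mean and coarsens the lesion texture for
    poor responders.  Identical specs generate bitwise-identical cohorts.
    """

    n_patients: int = SAHSYU_N
    prevalence: float = SAHSYU_POOR / SAHSYU_N
    effect: tuple[float, float, float] = (1.2, 0.66, 0.25)
    noise_sd: float = 1.0
    lesion_sd: float = 1.0  # patient-level lesion-intensity variability (in noise SDs)
    lesion_radius: tuple[float, float] = (8.0, 16.0)
    image_size: int = 96
    lesion_contrast: float = 2.0
    texture_sigma: float = 1.0
    texture_gain: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if any(e < 0 for e in self.effect):
            raise ValueError("effect sizes must be >= 0")
        if self.lesion_radius[1] * 2 >= min(self.image_size, PATCH_SIZE):
            raise ValueError("lesion radius range exceeds the patch size")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


@dataclass
class FeatureTableSpec:
    """Generation parameters for synthetic 3 x n feature-matrix cohorts.

    The informative block of each channel measures one patient-level
    latent (loading ``informative_loading``) whose mean is shifted by
    ``signal[c]`` SD units in poor responders, so redundant features
    saturate rather than stack — the attainable AUC is bounded by the
    combined latent shift (about 0.84 at the defaults), matching the
    performance regime the clinical models operate in.  The remaining
    features share a class-independent nuisance factor (``correlation``).
    """

    n_patients: int = SAHSYU_N
    n_features: int = 372
    n_informative: int = 20
    signal: tuple[float, float, float] = (1.2, 0.66, 0.25)
    informative_loading: float = 0.7
    correlation: float = 0.3
    prevalence: float = SAHSYU_POOR / SAHSYU_N
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("informative count exceeds n_features")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must be in [0, 1)")
        if not 0 <= self.informative_loading <= 1:
            raise ValueError("informative_loading must be in [0, 1]")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")


def _labels(n: int, prevalence: float, rng: np.random.Generator) -> np.ndarray:
    """Exact-count labels: round(n * prevalence) poor responders, shuffled."""
    n_poor = int(round(n * prevalence))
    y = np.zeros(n, dtype=int)
    y[:n_poor] = 1
    rng.shuffle(y)
    return y


def _draw_clinical(pid: str, label: int, rng: np.random.Generator) -> ClinicalRecord:
    # marginals loosely matched to the printed cohort characteristics;
    # independent of the response label (clinical variables non-predictive)
    return ClinicalRecord(
        patient_id=pid,
        sex="male" if rng.random() < 0.75 else "female",
        age=float(np.clip(rng.normal(55.0, 11.0), 20.0, 90.0)),
        cea="positive" if rng.random() < 0.45 else "negative",
        cT=rng.choice(["T2", "T3", "T4"], p=[0.06, 0.70, 0.24]),
        cN=rng.choice(["N0", "N1", "N2"], p=[0.22, 0.40, 0.38]),
        response=int(label),
    )


def _lesion_mask(size: int, rng: np.random.Generator, radius: tuple[float, float]):
    ra = rng.uniform(*radius)
    rb = rng.uniform(*radius)
    theta = rng.uniform(0, np.pi)
    cr = size / 2 + rng.uniform(-6, 6)
    cc = size / 2 + rng.uniform(-6, 6)
    rr, cc_grid = np.mgrid[0:size, 0:size]
    dr, dc = rr - cr, cc_grid - cc
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / ra) ** 2 + (v / rb) ** 2 <= 1.0


def generate_phantom_slices(
    spec: PhantomSpec,
) -> tuple[list[dict[str, AnnotatedSlice]], np.ndarray, list[ClinicalRecord]]:
    """Per-patient sequence slices (shared mask), labels and covariates."""
    rng = np.random.default_rng(spec.seed)
    y = _labels(spec.n_patients, spec.prevalence, rng)
    base_intensity = {"T2w": 100.0, "T1c": 80.0, "ADC": 60.0}
    cohort, records = [], []
    for i in range(spec.n_patients):
        pid = f"P{i:04d}"
        mask = _lesion_mask(spec.image_size, rng, spec.lesion_radius)
        slices: dict[str, AnnotatedSlice] = {}
        for ci, seq in enumerate(SEQUENCES):
            img = base_intensity[seq] + rng.normal(0, spec.noise_sd, (spec.image_size,) * 2)
            # patient-level lesion-intensity variability keeps the attainable
            # AUC finite: the class shift competes with biological variation
            offset = rng.normal(0.0, spec.lesion_sd * spec.noise_sd)
            shift = spec.effect[ci] * spec.noise_sd * y[i] + offset
            sigma = spec.texture_sigma * (1.0 + spec.texture_gain * spec.effect[ci] * y[i])
            tex = ndimage.gaussian_filter(rng.normal(0, 1, (spec.image_size,) * 2), sigma)
            sd = tex.std()
            if sd > 0:
                tex = tex / sd * spec.noise_sd
            img = np.where(mask, base_intensity[seq] + spec.lesion_contrast + shift + tex, img)
            slices[seq] = AnnotatedSlice(img, mask, (1.0, 1.0), seq)
        cohort.append(slices)
        records.append(_draw_clinical(pid, int(y[i]), rng))
    return cohort, y, records


def _patch_window(mask: np.ndarray) -> tuple[int, int]:
    rows, cols = np.nonzero(mask)
    return (
        int(round(rows.mean())) - PATCH_SIZE // 2,
        int(round(cols.mean())) - PATCH_SIZE // 2,
    )


def generate_phantom_cohort(
    spec: PhantomSpec, normalize: bool = True
) -> tuple[list[MultiSequencePatch], list[ClinicalRecord], dict]:
    """Cropped 80 x 80 patches plus ground truth for attention/saliency tests.

    The ground-truth dict records the per-channel effect vector, the index
    of the most informative channel and each lesion's bounding box in
    patch coordinates (rmin, rmax, cmin, cmax inclusive).
    """
    cohort, y, records = generate_phantom_slices(spec)
    patches, bboxes = [], []
    for i, slices in enumerate(cohort):
        patch = crop_patch(slices, label=int(y[i]), patient_id=records[i].patient_id,
                           normalize=normalize)
        patches.append(patch)
        mask = slices[SEQUENCES[0]].mask
        r0, c0 = _patch_window(mask)
        rows, cols = np.nonzero(mask)
        bboxes.append(
            (
                int(np.clip(rows.min() - r0, 0, PATCH_SIZE - 1)),
                int(np.clip(rows.max() - r0, 0, PATCH_SIZE - 1)),
                int(np.clip(cols.min() - c0, 0, PATCH_SIZE - 1)),
                int(np.clip(cols.max() - c0, 0, PATCH_SIZE - 1)),
            )
        )
    truth = {
        "effect": list(spec.effect),
        "informative_channel": int(np.argmax(spec.effect)),
        "lesion_bbox": bboxes,
    }
    return patches, records, truth


def generate_feature_table(
    spec: FeatureTableSpec,
) -> tuple[list[FeatureMatrix], np.ndarray, dict]:
    """Synthetic 3 x n feature matrices with channel-specific class signal.

    Channel c of patient i draws a signal latent ``t ~ N(y_i * signal[c], 1)``;
    the first ``n_informative`` feature columns are ``a*t`` plus independent
    noise (unit total variance), i.e. redundant measurements of the same
    latent.  The remaining columns share a class-independent nuisance
    factor with equicorrelation ``correlation``.
    """
    rng = np.random.default_rng(spec.seed)
    y = _labels(spec.n_patients, spec.prevalence, rng)
    rho = spec.correlation
    a = spec.informative_loading
    k = spec.n_informative
    names = canonical_feature_names() if spec.n_features == 372 else tuple(
        f"f{j}" for j in range(spec.n_features)
    )
    matrices = []
    for i in range(spec.n_patients):
        t = rng.normal(np.asarray(spec.signal) * y[i], 1.0)[:, None]  # 3 x 1
        nuisance = rng.normal(0, 1, (3, 1))
        noise = rng.normal(0, 1, (3, spec.n_features))
        m = np.sqrt(rho) * nuisance + np.sqrt(1 - rho) * noise
        m[:, :k] = a * t + np.sqrt(1 - a**2) * noise[:, :k]
        matrices.append(FeatureMatrix(m, tuple(names), patient_id=f"P{i:04d}", label=int(y[i])))
    truth = {
        "signal": list(spec.signal),
        "informative_channel": int(np.argmax(spec.signal)),
        "informative_features": list(range(spec.n_informative)),
    }
    return matrices, y, truth


def default_cohort_specs(seed: int = 0) -> dict[str, PhantomSpec]:
    """The three study cohorts: development (-> train/internal) and external."""
    return {
        "development": PhantomSpec(n_patients=SAHSYU_N, prevalence=SAHSYU_POOR / SAHSYU_N,
                                   seed=seed),
        "external": PhantomSpec(n_patients=ZCH_N, prevalence=ZCH_POOR / ZCH_N,
                                seed=seed + 1),
    }


def write_phantom_dataset(spec: PhantomSpec, out_dir: str | Path, fmt: str = "nifti") -> None:
    """Write a phantom cohort as image+mask files, clinical CSV and truth JSON."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    cohort, y, records = generate_phantom_slices(spec)
    for i, slices in enumerate(cohort):
        pid = records[i].patient_id
        for seq in SEQUENCES:
            if fmt == "nifti":
                save_slice_nifti(
                    slices[seq],
                    out / "images" / f"{pid}_{seq}.nii.gz",
                    out / "images" / f"{pid}_{seq}_mask.nii.gz",
                )
            else:
                import imageio.v3 as iio

                img = slices[seq].pixels
                lo, hi = img.min(), img.max()
                scaled = ((img - lo) / (hi - lo) * 65535).astype(np.uint16)
                iio.imwrite(out / "images" / f"{pid}_{seq}.png", scaled)
                iio.imwrite(
                    out / "images" / f"{pid}_{seq}_mask.png",
                    (slices[seq].mask * 255).astype(np.uint8),
                )
    write_clinical_table(records, out / "clinical.csv")
    truth = {
        "effect": list(spec.effect),
        "informative_channel": int(np.argmax(spec.effect)),
        "labels": [int(v) for v in y],
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
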
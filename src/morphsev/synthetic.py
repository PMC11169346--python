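"""Synthetic cohorts of ordinal morphometry volumes with planted structure.

The generator emulates the study conditions a severity classifier faces:
left-hemisphere lesions of variable size on a shared tissue template, planted
gray-matter atrophy *motifs* that are matched on total atrophy but differ in
spatial arrangement (clustered vs dispersed), and a continuous WAB-AQ-like
outcome in [0, 100] binned at 25/50/75 into the four aphasia-severity
categories, with roughly 35% of subjects below the severe cut point of 50.

Because the motifs are matched on total atrophy, any classifier that only sees
summed tissue volumes cannot separate them; only the spatial arrangement
carries the planted signal.  That property is what the CNN-vs-SVM comparison
downstream is designed to probe, and it is asserted exactly in tests.

The template is deterministic given the grid shape; randomness enters only
through lesion growth, atrophy placement, and the outcome noise, with one
independent random stream per subject derived from ``(seed, subject_index)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import (
    CODE_CSF,
    CODE_GM,
    CODE_WM,
    MorphometryVolume,
    merge_tissue_and_lesion,
    save_nifti,
)

CATEGORY4 = ("very severe", "severe", "moderate", "mild")
#: WAB-AQ cut points separating the four categories
CUTS = (25.0, 50.0, 75.0)
SEVERE_CUT = 50.0


class InvalidConfigError(ValueError):
    pass


class LesionGrowthError(RuntimeError):
    pass


@dataclass(frozen=True)
class Motif:
    """A named spatial arrangement for planted gray-matter atrophy.

    kind "clustered" converts a compact ball of GM voxels around a random
    center; "dispersed" scatters the same number of conversions over the whole
    GM compartment.  ``harmful`` marks motifs that lower the outcome score.
    """

    name: str
    kind: str  # "clustered" | "dispersed"
    harmful: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("clustered", "dispersed"):
            raise InvalidConfigError(f"unknown motif kind {self.kind!r}")


DEFAULT_MOTIFS = (
    Motif("focal", kind="clustered", harmful=True),
    Motif("diffuse", kind="dispersed", harmful=False),
)


@dataclass
class SyntheticCohortConfig:
    """Study conditions for a synthetic cohort.

    Outcome model: wab_aq = clip(100 - a*lesion_fraction - b*[motif harmful]
    + Normal(0, sigma), 0, 100) where lesion_fraction is lesion volume over
    total brain voxels.  The default coefficients were calibrated once by
    simulation so that ~35% of subjects fall below the severe cut point and
    all four categories occur.
    """

    n_subjects: int = 231
    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 8.0
    severe_fraction_target: float = 0.35
    lesion_volume_range: tuple[int, int] = (40, 400)
    motif_catalog: tuple[Motif, ...] = DEFAULT_MOTIFS
    atrophy_voxels: int = 30
    outcome_coefficients: tuple[float, float, float] = (850.0, 26.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.severe_fraction_target < 1.0):
            raise InvalidConfigError("severe_fraction_target must be in (0,1)")
        if self.grid_shape[0] % 2 != 0:
            raise InvalidConfigError("left/right axis must have even length")
        if len(self.motif_catalog) < 1:
            raise InvalidConfigError("motif catalog is empty")
        if self.lesion_volume_range[0] < 1:
            raise InvalidConfigError("lesion volume must be >= 1 voxel")
        a, b, sigma = self.outcome_coefficients
        if not np.all(np.isfinite([a, b, sigma])) or sigma < 0:
            raise InvalidConfigError("invalid outcome coefficients")


@dataclass
class SyntheticSubject:
    subject_id: str
    volume: MorphometryVolume
    lesion_mask: np.ndarray
    lesion_volume: int
    motif_id: str
    wab_aq: float
    category4: str
    label2: str  # "severe" | "nonsevere"


# ---------------------------------------------------------------------------
# template


def generate_tissue_template(
    grid_shape: tuple[int, int, int], seed: int = 0
) -> np.ndarray:
    """Deterministic mirror-symmetric tissue template (codes 0/1/2/3).

    Geometry: an ellipsoidal brain with a WM core, a GM shell around it, a CSF
    margin, and two CSF ventricles near the midline.  Symmetric across the
    midsagittal plane by construction.  ``seed`` is accepted for interface
    uniformity; the template is deterministic given the shape.
    """
    nx, ny, nz = grid_shape
    if nx % 2 != 0:
        raise InvalidConfigError("first axis must be even (midline at half)")
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    # normalized ellipsoidal radius; semi-axes leave a 1-voxel background rim
    ax, ay, az = (nx - 2) / 2.0, (ny - 2) / 2.0, (nz - 2) / 2.0
    if min(ax, ay, az) <= 0:
        raise InvalidConfigError(f"grid {grid_shape} too small for a brain template")
    r = np.sqrt(
        ((ii - cx) / ax) ** 2 + ((jj - cy) / ay) ** 2 + ((kk - cz) / az) ** 2
    )
    grid = np.zeros(grid_shape, dtype=np.int16)
    grid[r < 1.0] = CODE_CSF
    grid[r < 0.82] = CODE_GM
    grid[r < 0.45] = CODE_WM
    # ventricles: small symmetric CSF boxes inside the WM core
    vy0, vy1 = int(ny * 0.42), int(ny * 0.58)
    vz0, vz1 = int(nz * 0.40), int(nz * 0.60)
    vx_half = max(1, nx // 12)
    grid[nx // 2 - vx_half : nx // 2 + vx_half, vy0:vy1, vz0:vz1] = CODE_CSF
    for code in (CODE_CSF, CODE_GM, CODE_WM):
        if not (grid == code).any():
            raise InvalidConfigError(
                f"grid {grid_shape} too small to contain tissue code {code}"
            )
    return grid


# ---------------------------------------------------------------------------
# lesions

_NEIGHBORS6 = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def sample_lesion(
    template: np.ndarray,
    volume_range: tuple[int, int],
    rng: np.random.Generator,
    max_attempts: int = 20,
) -> np.ndarray:
    """Grow a connected left-hemisphere lesion from a fronto-lateral seed.

    The target size is uniform over ``volume_range`` (inclusive).  Growth is a
    randomized flood fill restricted to brain voxels of the left hemisphere,
    emulating the compact territory of a middle-cerebral-artery stroke.
    """
    template = np.asarray(template)
    nx, ny, nz = template.shape
    left_brain = template > 0
    left_brain[nx // 2 :] = False
    n_left = int(left_brain.sum())
    lo, hi = int(volume_range[0]), int(volume_range[1])
    if hi > n_left:
        raise InvalidConfigError(
            f"lesion volume range up to {hi} exceeds left-hemisphere brain "
            f"voxel count {n_left}"
        )
    target = int(rng.integers(lo, hi + 1))
    for _ in range(max_attempts):
        mask = _grow_region(left_brain, target, rng)
        if mask is not None:
            return mask
    raise LesionGrowthError(f"could not grow a lesion of {target} voxels")


def _grow_region(
    allowed: np.ndarray, target: int, rng: np.random.Generator
) -> np.ndarray | None:
    nx, ny, nz = allowed.shape
    # lateral left fronto-temporal seed: low x (lateral-left), anterior y
    seed = np.array([int(nx * 0.2), int(ny * 0.62), int(nz * 0.45)])
    if not allowed[tuple(seed)]:
        cand = np.argwhere(allowed)
        d = np.abs(cand - seed).sum(axis=1)
        seed = cand[int(np.argmin(d))]
    mask = np.zeros(allowed.shape, dtype=bool)
    mask[tuple(seed)] = True
    frontier = [tuple(seed)]
    size = 1
    while size < target:
        if not frontier:
            return None
        idx = int(rng.integers(len(frontier)))
        vox = np.array(frontier[idx])
        nbrs = vox + _NEIGHBORS6
        valid = [
            tuple(p)
            for p in nbrs
            if (0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz)
            and allowed[tuple(p)]
            and not mask[tuple(p)]
        ]
        if not valid:
            frontier.pop(idx)
            continue
        new = valid[int(rng.integers(len(valid)))]
        mask[new] = True
        frontier.append(new)
        size += 1
    return mask


# ---------------------------------------------------------------------------
# atrophy motifs


class InsufficientGMError(ValueError):
    pass


def plant_atrophy(
    template: np.ndarray, motif: Motif, n_voxels: int, rng: np.random.Generator
) -> np.ndarray:
    """Convert exactly ``n_voxels`` GM voxels to CSF inside the motif support.

    Clustered motifs take the nearest GM voxels around a random GM center;
    dispersed motifs sample GM voxels uniformly over the whole compartment.
    Everything else is left untouched, so two motifs at equal ``n_voxels``
    produce volumes with identical global GM counts.
    """
    template = np.asarray(template)
    out = template.copy()
    if n_voxels == 0:
        return out
    gm = np.argwhere(template == CODE_GM)
    if len(gm) < n_voxels:
        raise InsufficientGMError(
            f"motif {motif.name!r} needs {n_voxels} GM voxels, found {len(gm)}"
        )
    if motif.kind == "clustered":
        center = gm[int(rng.integers(len(gm)))]
        d = np.linalg.norm(gm - center, axis=1)
        chosen = gm[np.argsort(d, kind="stable")[:n_voxels]]
    else:  # dispersed
        idx = rng.choice(len(gm), size=n_voxels, replace=False)
        chosen = gm[idx]
    out[tuple(chosen.T)] = CODE_CSF
    return out


# ---------------------------------------------------------------------------
# outcomes


def assign_outcome(
    lesion_volume: int,
    motif: Motif,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    brain_voxels: int,
) -> tuple[float, str, str]:
    """Linear-Gaussian WAB-AQ model with clipping to [0, 100].

    wab = clip(100 - a * lesion_fraction - b * [harmful] + N(0, sigma)).
    Labels follow the 25/50/75 cut points; severe means wab <= 50.
    """
    a, b, sigma = config.outcome_coefficients
    frac = lesion_volume / brain_voxels
    noise = float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
    wab = float(np.clip(100.0 - a * frac - b * float(motif.harmful) + noise, 0.0, 100.0))
    return wab, categorize(wab), severity_label(wab)


def categorize(wab_aq: float) -> str:
    if wab_aq <= CUTS[0]:
        return CATEGORY4[0]
    if wab_aq <= CUTS[1]:
        return CATEGORY4[1]
    if wab_aq <= CUTS[2]:
        return CATEGORY4[2]
    return CATEGORY4[3]


def severity_label(wab_aq: float) -> str:
    return "severe" if wab_aq <= SEVERE_CUT else "nonsevere"


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(config: SyntheticCohortConfig) -> list[SyntheticSubject]:
    """Generate ``config.n_subjects`` reproducible synthetic subjects.

    Each subject has an independent random stream seeded by
    ``(config.seed, subject_index)``, so cohorts are reproducible and
    parallel-safe, and motif assignment is recorded as ground truth.
    """
    template = generate_tissue_template(config.grid_shape, config.seed)
    brain_voxels = int((template > 0).sum())
    subjects: list[SyntheticSubject] = []
    n_motifs = len(config.motif_catalog)
    for i in range(config.n_subjects):
        rng = np.random.default_rng([config.seed, i])
        motif = config.motif_catalog[int(rng.integers(n_motifs))]
        tissue = plant_atrophy(template, motif, config.atrophy_voxels, rng)
        lesion = sample_lesion(tissue, config.lesion_volume_range, rng)
        vol = merge_tissue_and_lesion(tissue, lesion, config.voxel_size_mm)
        lesion_volume = int(lesion.sum())
        wab, cat4, lab2 = assign_outcome(
            lesion_volume, motif, config, rng, brain_voxels
        )
        subjects.append(
            SyntheticSubject(
                subject_id=f"sub-{i:04d}",
                volume=vol,
                lesion_mask=lesion,
                lesion_volume=lesion_volume,
                motif_id=motif.name,
                wab_aq=wab,
                category4=cat4,
                label2=lab2,
            )
        )
    return subjects


def cohort_table(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "wab_aq": [s.wab_aq for s in subjects],
            "category4": [s.category4 for s in subjects],
            "label2": [s.label2 for s in subjects],
            "lesion_volume": [s.lesion_volume for s in subjects],
            "motif_id": [s.motif_id for s in subjects],
        }
    )


def save_cohort(subjects: list[SyntheticSubject], config: SyntheticCohortConfig,
                out_dir: str | Path) -> None:
    """Write one NIfTI per subject, the phenotype CSV, and a config sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        save_nifti(s.volume, str(out / f"{s.subject_id}.nii"))
    cohort_table(subjects).to_csv(out / "cohort.csv", index=False)
    cfg = asdict(config)
    cfg["motif_catalog"] = [asdict(m) for m in config.motif_catalog]
    (out / "config.json").write_text(json.dumps(cfg, indent=2))
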
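"""Synthetic BioID experiments and micrographs with known ground truth.

The count generator emulates the study design of a polycystin BioID screen:
a handful of baits each run in biological replicates under cycling and
ciliated (serum-deprived) conditions, plus a panel of promiscuous-ligase
negative controls (split across the two conditions, as in the emulated
design: five cycling, four ciliated out of nine).  Background counts for
every prey are negative binomial; a planted subset of true interactors per
bait has its mean inflated by ``effect_multiplier`` in test runs, and
additionally by ``condition_effect`` in ciliated runs.  The dispersion knob
is the negative-binomial size (variance mu + mu^2/size): Poisson sampling
plus multiplicative between-replicate noise of CV 1/sqrt(size).  The
default of 10 (~32% replicate CV) reflects the reproducibility typical of
spectral-count replicates; ``math.inf`` gives the Poisson limit.

The image generator produces single-plane two-channel crops: one filled
nuclear disc, and a lysosome channel of Gaussian puncta with a controlled
fraction centred inside the 30-pixel perinuclear ring.  The exact fraction
of (pre-noise) punctum intensity inside the analytic ring mask is returned
as ground truth for the ring-fraction pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .experiment import SpectralCountExperiment, ValidationError


@dataclass(frozen=True)
class SimulationDesign:
    """Study-design parameters of the synthetic spectral-count generator."""

    n_baits: int = 2
    n_replicates_per_condition: int = 2
    n_controls: int = 9
    n_preys: int = 2000
    n_true_per_bait: int = 50
    background_mean: float = 2.0
    effect_multiplier: float = 8.0
    dispersion: float = 10.0  # negative-binomial size; math.inf -> Poisson
    condition_effect: float = 1.0  # extra multiplier for planted preys, ciliated runs
    detection_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_baits, self.n_replicates_per_condition, self.n_controls,
               self.n_preys) < 1:
            raise ValidationError("design sizes must be positive")
        if not 0 <= self.n_true_per_bait <= self.n_preys:
            raise ValidationError("n_true_per_bait must be in [0, n_preys]")
        if self.background_mean <= 0 or self.effect_multiplier < 1:
            raise ValidationError("means must be positive, effect_multiplier >= 1")
        if self.dispersion <= 0:
            raise ValidationError("dispersion (negative-binomial size) must be > 0")
        if not 0 <= self.detection_dropout < 1:
            raise ValidationError("detection_dropout must be in [0, 1)")


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, size: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if not np.isfinite(size):
        return rng.poisson(mu)
    return rng.negative_binomial(size, size / (size + mu))


def simulate_experiment(
    design: SimulationDesign,
) -> tuple[SpectralCountExperiment, set[tuple[str, str]]]:
    """Generate an experiment plus the set of planted (bait, prey) truths."""
    rng = np.random.default_rng(design.seed)
    preys = [f"prey{i:04d}" for i in range(design.n_preys)]
    baits = [f"bait{i + 1:02d}" for i in range(design.n_baits)]

    truth: set[tuple[str, str]] = set()
    planted: dict[str, np.ndarray] = {}
    for bait in baits:
        idx = rng.choice(design.n_preys, size=design.n_true_per_bait, replace=False)
        planted[bait] = idx
        truth |= {(bait, preys[i]) for i in idx}

    rows, manifest_rows = [], []

    def add_run(run_id, bait_id, role, condition, mu):
        counts = _draw_counts(rng, mu, design.dispersion)
        if design.detection_dropout > 0:
            drop = rng.random(counts.shape) < design.detection_dropout
            counts = np.where(drop, 0, counts)
        rows.append(counts)
        manifest_rows.append((run_id, bait_id, role, condition))

    # negative controls: split across conditions (cycling gets the extra run)
    n_cyc = (design.n_controls + 1) // 2
    bg = np.full(design.n_preys, design.background_mean)
    for i in range(design.n_controls):
        condition = "cycling" if i < n_cyc else "ciliated"
        add_run(f"ctrl_{i + 1:02d}", "BirA_ctrl", "control", condition, bg)

    for bait in baits:
        for condition in ("cycling", "ciliated"):
            mu = bg.copy()
            mu[planted[bait]] *= design.effect_multiplier
            if condition == "ciliated":
                mu[planted[bait]] *= design.condition_effect
            for r in range(design.n_replicates_per_condition):
                add_run(f"{bait}_{condition}_r{r + 1}", bait, "test", condition, mu)

    run_ids = [m[0] for m in manifest_rows]
    counts = pd.DataFrame(np.vstack(rows), index=run_ids, columns=preys)
    manifest = pd.DataFrame(
        manifest_rows, columns=["run_id", "bait_id", "role", "condition"]
    ).set_index("run_id")
    return SpectralCountExperiment(counts=counts, manifest=manifest), truth


# ----------------------------------------------------------------------
# fluorescence images


@dataclass(frozen=True)
class ImageDesign:
    """Parameters of one synthetic two-channel cell crop (16-bit, single plane)."""

    image_size: int = 256
    nucleus_radius: int = 40
    ring_width: int = 30
    n_puncta: int = 150
    perinuclear_fraction: float = 0.5
    punctum_intensity: float = 2000.0
    punctum_sigma: float = 2.0
    nucleus_intensity: float = 3000.0
    background_level: float = 100.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_puncta < 0 or not 0 <= self.perinuclear_fraction <= 1:
            raise ValidationError("invalid puncta specification")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValidationError("background and noise must be non-negative")
        margin = self.image_size / 2 - (self.nucleus_radius + self.ring_width)
        if margin < 2:
            raise ValidationError(
                "nucleus plus ring must fit in the frame with a margin"
            )


def _add_punctum(img: np.ndarray, cy: float, cx: float, amp: float, sigma: float):
    n = img.shape[0]
    half = int(np.ceil(4 * sigma))
    y0, y1 = max(0, int(cy) - half), min(n, int(cy) + half + 1)
    x0, x1 = max(0, int(cx) - half), min(n, int(cx) + half + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
    )


def simulate_cell_image(
    design: ImageDesign,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One synthetic cell: (nuclear channel, lysosome channel, truth fraction).

    ``truth`` is the exact fraction of pre-noise punctum intensity falling in
    the analytic ring (between the nuclear-disc radius and radius + ring
    width), computed by pixel summation.  Returns two uint16 images.
    """
    rng = np.random.default_rng(design.seed)
    n = design.image_size
    cy = cx = n / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dist = np.hypot(yy - cy, xx - cx)
    nucleus = dist <= design.nucleus_radius
    ring = (dist > design.nucleus_radius) & (
        dist <= design.nucleus_radius + design.ring_width
    )

    puncta = np.zeros((n, n), dtype=np.float64)
    n_peri = int(round(design.perinuclear_fraction * design.n_puncta))
    edge_margin = 3.0 * design.punctum_sigma + 2.0
    r_out_lo = design.nucleus_radius + design.ring_width + 1.0
    r_out_hi = n / 2.0 - edge_margin
    if design.n_puncta > n_peri and r_out_hi <= r_out_lo:
        raise ValidationError(
            "no room outside the ring to place extra-perinuclear puncta"
        )
    for i in range(design.n_puncta):
        theta = rng.uniform(0, 2 * np.pi)
        if i < n_peri:  # centred inside the ring band
            r = rng.uniform(design.nucleus_radius + 1.0,
                            design.nucleus_radius + design.ring_width - 1.0)
        else:  # centred beyond the ring, clear of the frame edge
            r = rng.uniform(r_out_lo, r_out_hi)
        _add_punctum(
            puncta, cy + r * np.sin(theta), cx + r * np.cos(theta),
            design.punctum_intensity, design.punctum_sigma,
        )

    total = puncta.sum()
    truth = float(puncta[ring].sum() / total) if total > 0 else 0.0

    def finalize(signal: np.ndarray) -> np.ndarray:
        img = design.background_level + signal
        if design.noise_sd > 0:
            img = img + rng.normal(0.0, design.noise_sd, size=signal.shape)
        return np.clip(np.round(img), 0, 65535).astype(np.uint16)

    nuclear_img = finalize(design.nucleus_intensity * nucleus)
    lysosome_img = finalize(puncta)
    return nuclear_img, lysosome_img, truth


def simulate_cell_suite(
    fractions, base_design: ImageDesign = ImageDesign(), seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """One cell per requested perinuclear fraction, with derived seeds."""
    out = []
    for i, f in enumerate(fractions):
        d = replace(base_design, perinuclear_fraction=float(f),
                    seed=(seed * 100003 + i) % (2**31 - 1))
        out.append(simulate_cell_image(d))
    return out


def save_channels(path, nuclear: np.ndarray, lysosome: np.ndarray) -> None:
    """Write the two channels as one multi-channel TIFF."""
    import tifffile

    tifffile.imwrite(path, np.stack([nuclear, lysosome]).astype(np.uint16))
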
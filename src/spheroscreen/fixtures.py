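"""Ground-truthed synthetic inputs: spheroid-like images and plate readings.

Every generated artifact carries its generating truth, so any downstream
estimate (segmented area, fitted logIC50, plate CV) can be scored without
external reference data.  All randomness flows from explicit integer seeds;
identical seeds give bit-identical images and readings.

Image model: a single dark elliptical body with a thin brighter rim on a
mid-gray background — the contrast polarity of a phase-contrast spheroid —
plus optional small dark debris discs kept clear of the body, and additive
Gaussian camera noise, quantised to 8-bit.  No optical physics is simulated;
the fixtures exercise the segmentation contract (contrast polarity, hole
filling, debris separation), not microscope realism.

Plate model: readings are laid out on a 96-well map (samples in rows A-F x
columns 1-9, vehicle controls in column 10, kill controls in column 11, a
cell-free media row H), with the mean response taken from a monophasic or
biphasic dose-response truth curve and perturbed by multiplicative noise of
a stated CV — the form in which plate variability is reported in practice.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from . import dose_response
from .imaging import GrayImage, segment_spheroid
from .io_cli import PlateLayout, PlateReading, WellRole, WellSpec

BACKGROUND = 180.0   # mid-gray background level (8-bit)
BODY = 60.0          # dark spheroid interior
RIM = 235.0          # bright phase-contrast rim
DEBRIS = BODY        # debris is spheroid material: dark against the background
RIM_THICKNESS = 2.0  # px, nominal
DEBRIS_GAP = 4.0     # px clearance between debris and the rim

#: default 9-level half-log dilution series, 0.03-300 uM
DEFAULT_CONCENTRATIONS = (0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0)
MEDIA_FLOOR = 500.0  # raw reader units at 0% viability / cell-free media
SPAN = 4500.0        # raw units from 0% to 100% viability


# ---------------------------------------------------------------------------
# Image fixtures
# ---------------------------------------------------------------------------

@dataclass
class ImageTruth:
    """Generating parameters of one synthetic spheroid image."""

    center: tuple[float, float]          # (x, y) pixels
    semi_axes: tuple[float, float]       # (a, b) pixels, a >= b
    orientation: float = 0.0             # radians, major-axis angle
    scale: float = 1.0                   # um per pixel
    debris_count: int = 0
    noise_sd: float = 0.0                # 8-bit intensity units
    seed: int = 0
    shape: tuple[int, int] = (512, 512)  # (rows, cols)

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")
        if self.debris_count < 0:
            raise ValueError("debris_count must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def aspect_ratio(self) -> float:
        a, b = self.semi_axes
        return a / b

    @property
    def true_area_px(self) -> float:
        """Exact ellipse area pi*a*b in pixels^2."""
        a, b = self.semi_axes
        return math.pi * a * b

    @property
    def true_area_um2(self) -> float:
        return self.true_area_px * self.scale ** 2


def _elliptic_distance(shape: tuple[int, int], center: tuple[float, float],
                       semi_axes: tuple[float, float], orientation: float
                       ) -> np.ndarray:
    rows, cols = np.mgrid[0: shape[0], 0: shape[1]]
    dx = cols - center[0]
    dy = rows - center[1]
    c, s = math.cos(orientation), math.sin(orientation)
    u = (dx * c + dy * s) / semi_axes[0]
    v = (-dx * s + dy * c) / semi_axes[1]
    return np.sqrt(u * u + v * v)


def generate_spheroid_image(truth: ImageTruth) -> GrayImage:
    """Render a synthetic single-spheroid image from its truth record.

    Raises
    ------
    ValueError
        If the ellipse (plus rim) does not fit in the frame with at least a
        3-pixel margin.
    """
    a, b = truth.semi_axes
    th = truth.orientation
    ex = math.sqrt((a * math.cos(th)) ** 2 + (b * math.sin(th)) ** 2)
    ey = math.sqrt((a * math.sin(th)) ** 2 + (b * math.cos(th)) ** 2)
    cx, cy = truth.center
    h, w = truth.shape
    margin = RIM_THICKNESS + 3.0
    if (cx - ex < margin or cx + ex > w - 1 - margin
            or cy - ey < margin or cy + ey > h - 1 - margin):
        raise ValueError(
            f"ellipse (semi-axes {a:.0f}x{b:.0f}, centre {cx:.0f},{cy:.0f}) "
            f"exceeds the {w}x{h} frame with a 3 px margin")

    rng = np.random.default_rng(truth.seed)
    img = np.full(truth.shape, BACKGROUND, dtype=float)
    d = _elliptic_distance(truth.shape, truth.center, truth.semi_axes, th)
    img[d <= 1.0 + RIM_THICKNESS / b] = RIM
    img[d <= 1.0] = BODY

    placed = 0
    attempts = 0
    while placed < truth.debris_count and attempts < 200 * max(1, truth.debris_count):
        attempts += 1
        r_deb = float(rng.uniform(2.0, 6.0))
        px = float(rng.uniform(r_deb + 2, w - 1 - r_deb - 2))
        py = float(rng.uniform(r_deb + 2, h - 1 - r_deb - 2))
        # keep the whole disc clear of the rim
        dc = _elliptic_distance((1, 1), (cx - px, cy - py), (a, b), th)[0, 0]
        if dc < 1.0 + (RIM_THICKNESS + DEBRIS_GAP + r_deb) / b:
            continue
        rows, cols = np.mgrid[0: h, 0: w]
        disc = (cols - px) ** 2 + (rows - py) ** 2 <= r_deb ** 2
        img[disc] = DEBRIS
        placed += 1

    if truth.noise_sd > 0:
        img = img + rng.normal(0.0, truth.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return GrayImage(pixels=img, scale=truth.scale,
                     source_id=f"synthetic_seed{truth.seed}")


def generate_empty_well_image(noise_sd: float, seed: int,
                              shape: tuple[int, int] = (512, 512),
                              scale: float = 1.0) -> GrayImage:
    """Background-only image: no spheroid-scale object, just camera noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    img = np.full(shape, BACKGROUND, dtype=float)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return GrayImage(pixels=img, scale=scale, source_id=f"empty_seed{seed}")


def random_image_truth(seed: int,
                       diameter_px: tuple[float, float] = (150.0, 800.0),
                       noise_sd: tuple[float, float] = (0.0, 10.0),
                       max_debris: int = 20,
                       max_aspect: float = 1.4,
                       scale: float = 1.0) -> ImageTruth:
    """Draw a random truth spanning the working size range.

    The frame is sized to the spheroid so large fixtures stay cheap;
    the centre is jittered a few pixels off the frame centre.
    """
    rng = np.random.default_rng(seed)
    diam = float(rng.uniform(*diameter_px))
    aspect = float(rng.uniform(1.0, max_aspect))
    r_eq = diam / 2.0
    a = r_eq * math.sqrt(aspect)
    b = r_eq / math.sqrt(aspect)
    # frame sized so the body fills at most ~40% of the pixels: a centred
    # spheroid is always the minority class, as in a real microscope field
    side = int(math.ceil(2.8 * a)) + 30
    jitter = rng.uniform(-4, 4, size=2)
    center = (side / 2 + float(jitter[0]), side / 2 + float(jitter[1]))
    return ImageTruth(
        center=center, semi_axes=(a, b),
        orientation=float(rng.uniform(0.0, math.pi)),
        scale=scale,
        debris_count=int(rng.integers(0, max_debris + 1)),
        noise_sd=float(rng.uniform(*noise_sd)),
        seed=int(rng.integers(2 ** 31)),
        shape=(side, side),
    )


def area_recovery_study(n: int = 200, seed: int = 0, **truth_kwargs
                        ) -> np.ndarray:
    """Relative area errors of the segmentation pipeline on n random fixtures.

    Returns |measured - true| / true area for each seeded image; the median
    of this array is the headline segmentation-fidelity figure.
    """
    rng = np.random.default_rng(seed)
    errors = np.empty(n)
    for i in range(n):
        truth = random_image_truth(int(rng.integers(2 ** 31)), **truth_kwargs)
        img = generate_spheroid_image(truth)
        m = segment_spheroid(img)
        if m.empty:
            errors[i] = 1.0  # a missed spheroid counts as total error
        else:
            errors[i] = abs(m.area_um2 - truth.true_area_um2) / truth.true_area_um2
    return errors


# ---------------------------------------------------------------------------
# Plate fixtures
# ---------------------------------------------------------------------------

@dataclass
class PlateTruth:
    """Generating parameters of one simulated plate run.

    The dose-response truth uses the logistic parameterisation in which
    decreasing viability carries a negative Hill slope; ``hill``/``nH*``
    default to -1 (cytotoxicity orientation, unit magnitude).
    """

    model: str = "monophasic"            # or "biphasic"
    top: float = 100.0                   # % viability
    bottom: float = 0.0
    logIC50: float = 0.5                 # log10 uM (monophasic)
    hill: float = -1.0
    # biphasic defaults trace the neural-stem-cell shape: a very sharp first
    # transition complete by ~0.3 uM (midpoint 0.1 uM, steep slope), a ~50%
    # shoulder across 0.3-3 uM, then a moderate decline to ~5% by 300 uM
    logIC50_1: float = -1.0
    logIC50_2: float = 1.5
    frac: float = 0.5
    nH1: float = -3.0
    nH2: float = -1.0
    cv_per_assay: float = 10.0           # % multiplicative noise
    replicates: int = 6
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("monophasic", "biphasic"):
            raise ValueError("model must be 'monophasic' or 'biphasic'")
        if not self.bottom < self.top:
            raise ValueError("bottom must be below top")
        if not 0.0 <= self.frac <= 1.0:
            raise ValueError("frac must lie in [0, 1]")
        if self.cv_per_assay < 0:
            raise ValueError("cv must be >= 0")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates")
        if len(self.concentrations) < 4:
            raise ValueError("need >= 4 concentrations")
        if self.replicates > 6 or len(self.concentrations) > 9:
            raise ValueError("the 96-well map holds <= 6 replicates x 9 levels")

    def viability(self, concentration_uM) -> np.ndarray | float:
        """True % viability at a concentration (uM) from the truth curve."""
        X = np.log10(np.asarray(concentration_uM, dtype=float))
        if self.model == "monophasic":
            return dose_response.model_4pl(X, self.top, self.bottom,
                                           self.logIC50, self.hill)
        return dose_response.model_biphasic(
            X, self.top, self.bottom, self.frac,
            self.logIC50_1, self.logIC50_2, self.nH1, self.nH2)


def with_seed(truth: PlateTruth, seed: int) -> PlateTruth:
    """Copy of a plate truth with a new seed (same stated world)."""
    return dataclasses.replace(truth, seed=seed)


def default_plate_truth(model: str = "4pl", cv: float = 10.0,
                        replicates: int = 6, seed: int = 0) -> PlateTruth:
    """The package's stated simulation world for each model family."""
    model_name = "monophasic" if model in ("4pl", "monophasic") else "biphasic"
    return PlateTruth(model=model_name, cv_per_assay=cv,
                      replicates=replicates, seed=seed)


def layout_for_truth(truth: PlateTruth, assay: str = "resazurin",
                     drug: str = "etoposide") -> PlateLayout:
    """96-well layout matching the simulated plate geometry."""
    layout = PlateLayout(plate_id="synthetic")
    rows = "ABCDEF"[: truth.replicates]
    for j, conc in enumerate(truth.concentrations, start=1):
        for r in rows:
            layout.add(f"{r}{j}", WellSpec(role=WellRole.SAMPLE,
                                           condition=drug,
                                           concentration_uM=float(conc),
                                           assay=assay))
    for r in rows:
        layout.add(f"{r}10", WellSpec(role=WellRole.NEGATIVE_CONTROL, assay=assay))
        layout.add(f"{r}11", WellSpec(role=WellRole.POSITIVE_CONTROL, assay=assay))
    for j in range(1, 13):
        layout.add(f"H{j}", WellSpec(role=WellRole.MEDIA_ONLY, assay=assay))
    return layout


def simulate_plate(truth: PlateTruth, assay: str = "resazurin",
                   run_id: str = "run1") -> list[PlateReading]:
    """Simulate raw plate-reader values for one run of the truth curve.

    The mean raw signal is ``MEDIA_FLOOR + SPAN * viability/100``;
    each well is perturbed multiplicatively by ``1 + (CV/100) * z`` with
    standard-normal z.  At CV 0 every reading sits exactly on the truth
    curve.  Wells are emitted in a fixed order (samples by concentration
    then replicate row, then controls, then the media row), so one seed
    gives one byte-identical plate.
    """
    rng = np.random.default_rng(truth.seed)
    cv = truth.cv_per_assay / 100.0
    layout = layout_for_truth(truth, assay=assay)
    readings: list[PlateReading] = []

    def emit(well: str, mean: float) -> None:
        spec = layout.wells[well]
        value = mean * (1.0 + cv * rng.standard_normal()) if cv > 0 else mean
        readings.append(PlateReading(
            well=well, role=spec.role, assay=spec.assay, value=float(value),
            condition=spec.condition, concentration_uM=spec.concentration_uM,
            run_id=run_id))

    rows = "ABCDEF"[: truth.replicates]
    for j, conc in enumerate(truth.concentrations, start=1):
        mean = MEDIA_FLOOR + SPAN * float(truth.viability(conc)) / 100.0
        for r in rows:
            emit(f"{r}{j}", mean)
    for r in rows:
        emit(f"{r}10", MEDIA_FLOOR + SPAN)  # vehicle control, 100% viability
    for r in rows:
        emit(f"{r}11", MEDIA_FLOOR)         # 25% DMSO kill control, 0%
    for j in range(1, 13):
        emit(f"H{j}", MEDIA_FLOOR)          # cell-free media row
    return readings
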
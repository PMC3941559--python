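"""Synthetic cohort generator: subjects, marker kinematics and rendered frames.

Emulates the study conditions of a supine adolescent cohort performing a
forced-breathing maneuver with five circular adhesive markers along the
trunk.  Anthropometrics are drawn from truncated normals matching the
cohort's published mean/SD/min/max; marker displacement between the
expiration and inspiration extremes is constructed by an inverse model of
the trapezoid-extrusion geometry so the forward volumetry reproduces a
prescribed total volumetric mobility exactly.  Frames are rendered as
anti-aliased dark circles on a light background so the detection stage can
be exercised with known ground truth.

All sampling is driven by explicit integer seeds through
``numpy.random.default_rng``; no global random state is touched.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InvalidConfigurationError, ParameterError
from .imaging import LANDMARKS, MARKER_DIAMETER_MM, MarkerSet
from .prediction import DI_MODEL, FVC_MODEL
from .volumetry import COMPARTMENTS, CompartmentVolumes, pair_breath, volumes_from_markers

# ---------------------------------------------------------------------------
# Cohort statistics the generator reproduces (mean, SD, min, max).
# ---------------------------------------------------------------------------

ANTHROPOMETRY = {
    "age": (15.4, 1.0, 14.0, 17.0),  # years
    "body_mass": (61.3, 12.3, 43.5, 87.0),  # kg
    "height": (1.66, 0.1, 1.52, 1.87),  # m
    "thorax_length": (25.5, 1.9, 21.5, 29.5),  # cm
}

#: Fraction of analyzed subjects that were boys (19 of 40).
P_MALE = 19.0 / 40.0

#: Expiration compartment volume means (l) defining the resting proportions.
EXPIRATION_MEANS_L = {"UT": 7.32, "LT": 5.90, "UA": 2.56, "LA": 3.56}

#: Inspiration − expiration compartment mean differences (l): the observed
#: recruitment pattern over which mobility is apportioned.
MOBILITY_SPLIT_L = {"UT": 1.09, "LT": 1.75, "UA": 0.60, "LA": 0.30}

#: Expiration thoracoabdominal total (l): mean, SD, min, max.
EXPIRATION_TOTAL_L = (19.33, 6.18, 10.36, 39.52)

#: Total volumetric mobility (l) sampled per subject: mean, SD, min, max.
#: The mean is the difference of the inspiration and expiration cohort
#: totals (23.08 − 19.33).  The SD is not published; 1.0 l is calibrated
#: jointly with the size-factor loading against the published FVC SD
#: (0.91 l) and the published mobility-FVC correlation (0.812), and its
#: ±3 SD range brackets the mobility implied by the per-phase extreme
#: totals (2.05 to 6.79 l).
MOBILITY_L = (3.75, 1.0, 0.5, 7.5)

#: Loading of body size variables (height, mass, thorax, mobility,
#: resting trunk volume) on a shared latent growth factor.  Adolescent
#: anthropometrics co-vary strongly with maturation; 0.9 reproduces the
#: published FVC SD and mobility-FVC correlation under the published
#: marginal SDs.
SIZE_FACTOR_LOADING = 0.9

#: Spirometric nuisance quantities: PEF (l/s) and the Tiffeneau ratio of the
#: retained (index >= 0.80) cohort.
PEF_LS = (6.50, 2.41, 2.84, 12.15)
TIFFENEAU = (0.832, 0.04, 0.80, 0.95)

#: Residual scatter (l) of the published FVC and DI regressions, used when
#: simulating measured spirometry around the model predictions.
FVC_RESIDUAL_SD = 0.353
DI_RESIDUAL_SD = 0.451

#: Relative marker heights MEd..EId of the supine profile template: chest
#: plateau dropping to the abdomen, as seen in a lateral view.
_PROFILE_SHAPE = np.array([1.00, 1.04, 0.96, 0.55, 0.60])

#: Trunk length (MEd to EId along the body axis) as a fraction of stature.
_TRUNK_FRACTION = 0.27

#: Physical cap on marker height above the bed (cm): a supine adolescent
#: trunk profile cannot plausibly rise higher than this (the published extreme resting
#: volumes imply profiles up to roughly 50 cm).
_MAX_MARKER_HEIGHT_CM = 60.0


@dataclass(frozen=True)
class SubjectSpec:
    """Ground-truth description of one synthetic subject."""

    subject_id: str
    sex: str
    age: int
    body_mass: float
    height: float
    thorax_length: float
    mm_per_px: float
    baseline_y: float = 0.0

    def __post_init__(self):
        if not 1.40 <= self.height <= 2.00:
            raise ParameterError(f"height {self.height} m outside [1.40, 2.00]")
        if not 18.0 <= self.thorax_length <= 32.0:
            raise ParameterError(f"thorax length {self.thorax_length} cm outside [18, 32]")
        if self.mm_per_px <= 0:
            raise ParameterError("mm_per_px must be positive")
        if not 14 <= self.age <= 17:
            raise ParameterError(f"age {self.age} outside [14, 17]")
        if self.sex not in ("M", "F"):
            raise ParameterError("sex must be 'M' or 'F'")


@dataclass(frozen=True)
class KinematicTruth:
    """Marker coordinates and volumes at both respiratory extremes."""

    marker_xy_exp: np.ndarray  # (5, 2) cm, landmark order
    marker_xy_insp: np.ndarray
    true_volumes_exp: CompartmentVolumes
    true_volumes_insp: CompartmentVolumes
    true_mobility: float

    def markerset(self, phase: str) -> MarkerSet:
        xy = self.marker_xy_exp if phase == "expiration" else self.marker_xy_insp
        return MarkerSet(
            coords={name: (float(x), float(y)) for name, (x, y) in zip(LANDMARKS, xy)},
            source="detected",
        )


@dataclass(frozen=True)
class RenderedFrame:
    """8-bit grayscale raster with five filled marker circles."""

    pixels: np.ndarray
    marker_px_diameter: float
    phase: str
    baseline_row_px: float = 0.0


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    """Rejection-sampled normal restricted to [lo, hi]."""
    for _ in range(10_000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    raise ParameterError("truncated-normal sampling failed to converge")


def _factor_normal(
    rng: np.random.Generator, z: float, mean, sd, lo, hi, loading=SIZE_FACTOR_LOADING
) -> float:
    """Truncated normal sharing the latent size factor ``z``.

    The factor value is kept fixed and only the idiosyncratic part is
    redrawn on rejection, so correlations survive the truncation.
    """
    resid = np.sqrt(1.0 - loading**2)
    for _ in range(100_000):
        v = mean + sd * (loading * z + resid * rng.normal())
        if lo <= v <= hi:
            return float(v)
    raise ParameterError("truncated-normal sampling failed to converge")


def truncated_normal_mean(mean, sd, lo, hi) -> float:
    """Analytic mean of the truncated normal (oracle for sampling checks)."""
    from scipy import stats

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))


def _sample_subject(rng: np.random.Generator, subject_id: str) -> tuple[SubjectSpec, float]:
    """One subject plus their latent size-factor value.

    Height, mass and thorax length load on a shared growth factor
    (joint rejection keeps every draw inside the published min/max); age
    is sampled independently over its narrow range.
    """
    resid = np.sqrt(1.0 - SIZE_FACTOR_LOADING**2)
    body_vars = ("body_mass", "height", "thorax_length")
    for _ in range(10_000):
        z = rng.normal()
        draws = {}
        ok = True
        for name in body_vars:
            mean, sd, lo, hi = ANTHROPOMETRY[name]
            v = mean + sd * (SIZE_FACTOR_LOADING * z + resid * rng.normal())
            if not lo <= v <= hi:
                ok = False
                break
            draws[name] = float(v)
        if ok:
            break
    else:  # pragma: no cover - acceptance rate is ~0.8
        raise ParameterError("subject sampling failed to converge")

    age = _truncated_normal(rng, *ANTHROPOMETRY["age"])
    subject = SubjectSpec(
        subject_id=subject_id,
        sex="M" if rng.random() < P_MALE else "F",
        age=int(round(age)),
        body_mass=draws["body_mass"],
        height=draws["height"],
        thorax_length=draws["thorax_length"],
        mm_per_px=float(rng.uniform(0.6, 1.0)),
    )
    return subject, float(z)


def sample_subject(rng_seed: int, subject_id: str = "S0001") -> SubjectSpec:
    """Draw one subject from the cohort anthropometric distributions."""
    rng = np.random.default_rng(rng_seed)
    subject, _ = _sample_subject(rng, subject_id)
    return subject


def _area_matrix(dx: np.ndarray) -> np.ndarray:
    """(4, 5) linear map from marker heights to trapezoid areas."""
    A = np.zeros((4, 5))
    for i in range(4):
        A[i, i] = dx[i] / 2.0
        A[i, i + 1] = dx[i] / 2.0
    return A


def make_kinematics(
    subject: SubjectSpec,
    target_mobility: float,
    rng_seed: int = 0,
    size_factor: float | None = None,
) -> KinematicTruth:
    """Inverse model: marker positions realizing a prescribed mobility.

    Expiration compartment volumes are proportioned as the cohort
    expiration means and scaled to a sampled resting total; marker x
    spacings are solved so a jittered supine profile template attains those
    areas over a trunk length of ~27% of stature.  The inspiration frame
    moves markers vertically only (the anterior wall displaces
    perpendicular to the bed), by the minimum-norm height correction whose
    area increments apportion ``target_mobility`` over the compartments in
    the observed recruitment proportions.  The forward volumetry therefore
    reproduces ``target_mobility`` to numerical precision.

    ``size_factor`` optionally ties the resting trunk volume to the
    subject's latent growth factor so larger subjects get larger trunks.
    """
    if target_mobility < 0:
        raise ParameterError("target mobility must be non-negative (litres)")
    rng = np.random.default_rng(rng_seed)
    L = subject.thorax_length

    if size_factor is None:
        exp_total = _truncated_normal(rng, *EXPIRATION_TOTAL_L)
    else:
        exp_total = _factor_normal(rng, size_factor, *EXPIRATION_TOTAL_L)
    fractions = np.array([EXPIRATION_MEANS_L[c] for c in COMPARTMENTS])
    fractions /= fractions.sum()
    exp_areas = fractions * exp_total * 1000.0 / L  # cm^2

    shape = _PROFILE_SHAPE * (1.0 + rng.uniform(-0.05, 0.05, size=5))
    midpoints = (shape[:-1] + shape[1:]) / 2.0
    trunk_length = _TRUNK_FRACTION * subject.height * 100.0  # cm
    h = float(np.sum(exp_areas / midpoints) / trunk_length)
    y_exp = h * shape
    dx = exp_areas / (h * midpoints)
    if np.any(dx <= MARKER_DIAMETER_MM / 10.0):
        raise InvalidConfigurationError("marker spacing too small for disjoint markers")

    split = np.array([MOBILITY_SPLIT_L[c] for c in COMPARTMENTS])
    split /= split.sum()
    delta_areas = split * target_mobility * 1000.0 / L

    A = _area_matrix(dx)
    # minimum-norm height correction satisfying the four area increments
    dy = A.T @ np.linalg.solve(A @ A.T, delta_areas)
    y_insp = y_exp + dy
    if np.any(y_insp <= 0):
        raise InvalidConfigurationError(
            "target mobility would push a marker to or below the support surface"
        )
    if np.any(y_insp > _MAX_MARKER_HEIGHT_CM) or np.any(y_exp > _MAX_MARKER_HEIGHT_CM):
        raise InvalidConfigurationError(
            "target mobility would lift a marker beyond a plausible supine profile "
            f"(> {_MAX_MARKER_HEIGHT_CM} cm above the bed)"
        )

    x = np.concatenate([[0.0], np.cumsum(dx)])
    xy_exp = np.column_stack([x, y_exp])
    xy_insp = np.column_stack([x, y_insp])

    def forward(xy):
        ms = MarkerSet(
            coords={name: (float(px), float(py)) for name, (px, py) in zip(LANDMARKS, xy)}
        )
        return volumes_from_markers(ms, L)

    vol_exp = forward(xy_exp)
    vol_insp = forward(xy_insp)
    pair = pair_breath(vol_exp, vol_insp)
    return KinematicTruth(
        marker_xy_exp=xy_exp,
        marker_xy_insp=xy_insp,
        true_volumes_exp=vol_exp,
        true_volumes_insp=vol_insp,
        true_mobility=pair.mobility,
    )


def render_frame(
    truth: KinematicTruth,
    phase: str,
    subject: SubjectSpec,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> RenderedFrame:
    """Rasterize one respiratory extreme as five filled circles.

    Circles have diameter 13 mm / mm_per_px and are drawn with analytic
    edge anti-aliasing (per-pixel disk coverage), so intensity-weighted
    centroids and coverage-weighted areas recover the ground truth to
    sub-pixel accuracy.  Additive Gaussian noise (SD in gray levels on the
    0-255 scale) is applied after drawing; output is an 8-bit raster.
    """
    if phase not in ("expiration", "inspiration"):
        raise ParameterError("phase must be 'expiration' or 'inspiration'")
    xy = truth.marker_xy_exp if phase == "expiration" else truth.marker_xy_insp
    px_per_cm = 10.0 / subject.mm_per_px
    radius = MARKER_DIAMETER_MM / subject.mm_per_px / 2.0

    centers = xy * px_per_cm  # (x_px from MEd, y_px above baseline)
    d2 = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d2, np.inf)
    if d2.min() <= 2 * radius + 2:
        raise InvalidConfigurationError("markers too close for disjoint circles")

    margin = int(np.ceil(3 * radius)) + 10
    width = int(np.ceil(centers[:, 0].max())) + 2 * margin
    height = int(np.ceil(centers[:, 1].max())) + 2 * margin
    baseline_row = float(height - margin)

    cols = margin + centers[:, 0]
    rows = baseline_row - centers[:, 1]

    # background below 255 so additive noise rarely clips at the ceiling
    bg_level = 235.0
    img = np.full((height, width), bg_level)
    yy, xx = np.mgrid[0:height, 0:width]
    for r0, c0 in zip(rows, cols):
        # restrict to a local patch around the circle for speed
        r_lo, r_hi = int(r0 - radius) - 2, int(r0 + radius) + 3
        c_lo, c_hi = int(c0 - radius) - 2, int(c0 + radius) + 3
        patch_y = yy[r_lo:r_hi, c_lo:c_hi]
        patch_x = xx[r_lo:r_hi, c_lo:c_hi]
        dist = np.hypot(patch_y - r0, patch_x - c0)
        coverage = np.clip(radius + 0.5 - dist, 0.0, 1.0)
        img[r_lo:r_hi, c_lo:c_hi] -= bg_level * coverage

    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return RenderedFrame(
        pixels=img,
        marker_px_diameter=2 * radius,
        phase=phase,
        baseline_row_px=baseline_row,
    )


def sample_regression_cohort(n: int, rng_seed: int) -> np.ndarray:
    """Predictor draws with the published cohort dispersion, for
    regression-form recovery simulations.

    Returns an (n, 3) array of (height m, thorax cm, mobility l) sampled
    as correlated normals with the published means and SDs and the shared
    size factor, WITHOUT range truncation: the published min/max are
    sample extremes of a 40-subject cohort, and clipping at them shaves
    roughly 15% off every SD, which would understate the predictor spread
    that the published model fits were obtained under.  Not used for
    rendering (no subject validity bounds are enforced).
    """
    if n < 1:
        raise ParameterError("cohort size must be at least 1")
    rng = np.random.default_rng(rng_seed)
    rho = SIZE_FACTOR_LOADING
    resid = np.sqrt(1.0 - rho**2)
    z = rng.normal(size=n)
    cols = []
    for mean, sd in (
        (ANTHROPOMETRY["height"][0], ANTHROPOMETRY["height"][1]),
        (ANTHROPOMETRY["thorax_length"][0], ANTHROPOMETRY["thorax_length"][1]),
        (MOBILITY_L[0], MOBILITY_L[1]),
    ):
        cols.append(mean + sd * (rho * z + resid * rng.normal(size=n)))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Cohort-level fixture generation
# ---------------------------------------------------------------------------


def sample_cohort(n: int, rng_seed: int) -> list[tuple[SubjectSpec, KinematicTruth, dict]]:
    """Draw ``n`` subjects with kinematics and simulated spirometry.

    Measured FVC and DI are generated as the published regression
    predictions plus Gaussian residuals with the published scatter, so a
    refit on a synthetic cohort recovers the model form; FEV1 follows from
    a sampled Tiffeneau ratio of the retained range and PEF is an
    independent truncated normal.
    """
    if n < 1:
        raise ParameterError("cohort size must be at least 1")
    root = np.random.default_rng(rng_seed)
    out = []
    for i in range(n):
        sub_seed, kin_seed = root.integers(0, 2**31 - 1, size=2)
        subject, z = _sample_subject(
            np.random.default_rng(int(sub_seed)), f"S{i + 1:04d}"
        )
        rng = np.random.default_rng(int(kin_seed))
        mobility = _factor_normal(rng, z, *MOBILITY_L)
        truth = make_kinematics(
            subject,
            mobility,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
            size_factor=z,
        )
        fvc = max(
            0.5,
            FVC_MODEL.predict(subject.height, subject.thorax_length, mobility)
            + rng.normal(0.0, FVC_RESIDUAL_SD),
        )
        di = max(
            0.5,
            DI_MODEL.predict(subject.height, subject.thorax_length, mobility)
            + rng.normal(0.0, DI_RESIDUAL_SD),
        )
        spiro = {
            "FVC_l": fvc,
            "FEV1_l": fvc * _truncated_normal(rng, *TIFFENEAU),
            "PEF_ls": _truncated_normal(rng, *PEF_LS),
            "DI_l": di,
        }
        out.append((subject, truth, spiro))
    return out


def write_fixture_set(
    n: int, rng_seed: int, out_dir: str | Path, noise_sd: float = 0.0
) -> dict[str, Path]:
    """Write a complete synthetic study to ``out_dir``.

    Produces subjects.csv (anthropometrics + spirometry), truth_markers.csv
    (one row per marker per phase), truth_volumes.csv, paired PNG frames,
    and frames_index.csv linking each frame to its baseline row.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames_dir = out / "frames"
    frames_dir.mkdir(exist_ok=True)
    cohort = sample_cohort(n, rng_seed)

    subj_path = out / "subjects.csv"
    with open(subj_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "subject_id",
                "sex",
                "age",
                "body_mass_kg",
                "height_m",
                "thorax_cm",
                "FEV1_l",
                "FVC_l",
                "PEF_ls",
                "DI_l",
            ]
        )
        for subject, _, spiro in cohort:
            w.writerow(
                [
                    subject.subject_id,
                    subject.sex,
                    subject.age,
                    f"{subject.body_mass:.1f}",
                    f"{subject.height:.4f}",
                    f"{subject.thorax_length:.2f}",
                    f"{spiro['FEV1_l']:.4f}",
                    f"{spiro['FVC_l']:.4f}",
                    f"{spiro['PEF_ls']:.4f}",
                    f"{spiro['DI_l']:.4f}",
                ]
            )

    markers_path = out / "truth_markers.csv"
    with open(markers_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "phase", "landmark", "x_cm", "y_cm"])
        for subject, truth, _ in cohort:
            for phase, xy in (
                ("expiration", truth.marker_xy_exp),
                ("inspiration", truth.marker_xy_insp),
            ):
                for name, (x, y) in zip(LANDMARKS, xy):
                    w.writerow([subject.subject_id, phase, name, f"{x:.6f}", f"{y:.6f}"])

    volumes_path = out / "truth_volumes.csv"
    with open(volumes_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "subject_id",
                "phase",
                "UT_l",
                "LT_l",
                "TT_l",
                "UA_l",
                "LA_l",
                "TA_l",
                "thoracoabdominal_l",
                "mobility_l",
            ]
        )
        for subject, truth, _ in cohort:
            for phase, vol in (
                ("expiration", truth.true_volumes_exp),
                ("inspiration", truth.true_volumes_insp),
            ):
                row = [subject.subject_id, phase] + [
                    f"{vol.as_dict()[k]:.6f}"
                    for k in ("UT", "LT", "TT", "UA", "LA", "TA", "thoracoabdominal")
                ]
                row.append(f"{truth.true_mobility:.6f}" if phase == "inspiration" else "")
                w.writerow(row)

    index_path = out / "frames_index.csv"
    render_root = np.random.default_rng(rng_seed + 1)
    with open(index_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "phase", "path", "baseline_row_px", "axis_direction"])
        for subject, truth, _ in cohort:
            for phase in ("expiration", "inspiration"):
                frame = render_frame(
                    truth,
                    phase,
                    subject,
                    noise_sd=noise_sd,
                    rng_seed=int(render_root.integers(0, 2**31 - 1)),
                )
                fname = f"{subject.subject_id}_{phase}.png"
                iio.imwrite(frames_dir / fname, frame.pixels)
                w.writerow(
                    [
                        subject.subject_id,
                        phase,
                        f"frames/{fname}",
                        f"{frame.baseline_row_px:.1f}",
                        "x_increasing_caudal",
                    ]
                )

    return {
        "subjects": subj_path,
        "truth_markers": markers_path,
        "truth_volumes": volumes_path,
        "frames_index": index_path,
        "frames_dir": frames_dir,
    }
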
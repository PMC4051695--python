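"""Synthetic data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here with the
truth attached, so each downstream stage is testable without any real
microscopy or assay data:

* periodic striation intensity profiles and 2-D fibril images (bright
  Z-disc peaks, thin-filament plateau, dark H-zone trough, Gaussian PSF
  blur, additive noise) in phalloidin and obscurin flavours;
* pulse-chase turnover time courses with a lag → linear rise → exponential
  decay kinetic shape (or a non-decaying plateau emulating a cytoplasmic
  eGFP control);
* qPCR Ct tables under the doubling model with Gaussian cycle noise;
* per-vial negative-geotaxis outcomes as binomial draws;
* a whole-screen fixture whose genes carry class-structured day-of-loss
  values, GO annotations and interaction edges.

All generators take an explicit integer seed and are bit-reproducible; no
global random state is touched.  Positions are continuous µm, sampled at
pixel centres with index 0 at the profile start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .geotaxis import (
    DEFAULT_ASSAY_DAYS,
    SEVERITY_CLASSES,
    ScreenGene,
    severity_window_days,
)
from .morphometry import IntensityProfile
from .turnover import PulseChaseSeries

__all__ = [
    "StriationTruth",
    "TurnoverKinetics",
    "QpcrDesign",
    "ClimbingDesign",
    "ScreenFixture",
    "SyntheticImage",
    "gen_striation_profile",
    "gen_mline_profile",
    "gen_striation_image",
    "gen_pulse_chase",
    "gen_ct_table",
    "gen_geotaxis",
    "gen_screen_fixture",
    "DEFAULT_GO_VOCABULARY",
]

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # sigma -> FWHM factor


@dataclass(frozen=True)
class StriationTruth:
    """Ground-truth sarcomere geometry and imaging parameters.

    Lengths are µm, intensities arbitrary units.  The closure identity
    ``sarcomere_length = 2·thin_filament_length + h_zone_width`` must hold
    exactly (use :meth:`from_period` to construct a consistent record from
    a period and an H-zone width).
    """

    sarcomere_length: float
    thin_filament_length: float
    h_zone_width: float
    z_disc_width: float = 0.3  # FWHM of the Z-disc peak, µm
    z_peak_level: float = 1.0
    filament_level: float = 0.6
    h_zone_level: float = 0.15
    background: float = 0.05
    psf_sigma: float = 0.05
    pixel_size: float = 0.05

    def __post_init__(self) -> None:
        closure = 2.0 * self.thin_filament_length + self.h_zone_width
        if abs(closure - self.sarcomere_length) > 1e-9:
            raise ValueError("truth must satisfy SL = 2*TFL + HZ")
        if not (
            self.z_peak_level > self.filament_level > self.h_zone_level >= self.background >= 0
        ):
            raise ValueError("levels must satisfy z_peak > filament > h_zone >= background >= 0")
        if self.pixel_size <= 0 or self.psf_sigma < 0:
            raise ValueError("pixel_size must be > 0 and psf_sigma >= 0")
        if min(self.sarcomere_length, self.thin_filament_length, self.z_disc_width) <= 0:
            raise ValueError("lengths must be positive")
        if self.h_zone_width < 0:
            raise ValueError("h_zone_width must be >= 0")

    @classmethod
    def from_period(cls, sarcomere_length: float, h_zone_width: float = 0.16, **kw) -> "StriationTruth":
        """Build a closure-consistent truth from SL and HZ."""
        tfl = (sarcomere_length - h_zone_width) / 2.0
        return cls(sarcomere_length, tfl, h_zone_width, **kw)


@dataclass(frozen=True)
class TurnoverKinetics:
    """Minimal pulse-chase kinetic shape: lag, linear rise, exponential decay.

    ``decays=False`` freezes the signal at the peak after ``rise_end``,
    emulating a stable cytoplasmic eGFP control.  ``body_fraction`` scales
    the sarcomere-body intensity relative to the Z-disc.
    """

    lag: float = 20.0  # h without signal above baseline
    rise_end: float = 95.0  # h of the intensity maximum
    decay_halflife: float = 72.0  # h, post-peak
    baseline: float = 10.0
    peak: float = 100.0
    body_fraction: float = 0.4
    decays: bool = True

    def __post_init__(self) -> None:
        if not self.lag < self.rise_end:
            raise ValueError("lag must precede rise_end")
        if not self.peak > self.baseline >= 0:
            raise ValueError("need peak > baseline >= 0")
        if self.decay_halflife <= 0:
            raise ValueError("decay_halflife must be positive")
        if not 0 < self.body_fraction <= 1:
            raise ValueError("body_fraction must lie in (0, 1]")

    def mean_z(self, t: float) -> float:
        """Noise-free Z-disc intensity at time t (hours)."""
        if t <= self.lag:
            return self.baseline
        if t <= self.rise_end:
            frac = (t - self.lag) / (self.rise_end - self.lag)
            return self.baseline + frac * (self.peak - self.baseline)
        if not self.decays:
            return self.peak
        decay = 2.0 ** (-(t - self.rise_end) / self.decay_halflife)
        return self.baseline + (self.peak - self.baseline) * decay


@dataclass(frozen=True)
class QpcrDesign:
    """Design of a comparative-Ct qPCR experiment.

    ``expression`` maps ``(gene, genotype, day)`` to true relative
    expression with the calibrator condition at 1.  The reference gene is
    implicitly at 1 in every condition.
    """

    targets: tuple[str, ...]
    reference: str
    conditions: tuple[tuple[str, int], ...]  # (genotype, day)
    expression: Mapping[tuple[str, str, int], float]
    base_ct: Mapping[str, float]
    replicate_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.reference in self.targets:
            raise ValueError("reference gene must not be listed among targets")
        for gene in self.targets:
            for genotype, day in self.conditions:
                expr = self.expression.get((gene, genotype, day))
                if expr is None or expr <= 0:
                    raise ValueError(f"expression for {(gene, genotype, day)} must be positive")
        for gene in (*self.targets, self.reference):
            if gene not in self.base_ct:
                raise ValueError(f"missing base_ct for {gene}")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")


@dataclass(frozen=True)
class ClimbingDesign:
    """Negative-geotaxis assay design: success probability per assay day."""

    days: tuple[int, ...] = DEFAULT_ASSAY_DAYS
    p_success: tuple[float, ...] = ()
    n_vials: int = 10
    flies_per_vial: int = 10
    tech_reps: int = 5
    line: str = "line"

    def __post_init__(self) -> None:
        if len(self.p_success) != len(self.days):
            raise ValueError("p_success must align with days")
        if any(not 0 <= p <= 1 for p in self.p_success):
            raise ValueError("p_success values must lie in [0, 1]")
        if min(self.n_vials, self.flies_per_vial, self.tech_reps) < 1:
            raise ValueError("counts must be >= 1")

    @classmethod
    def linear_decline(
        cls,
        p_start: float,
        p_end: float,
        days: Sequence[int] = DEFAULT_ASSAY_DAYS,
        **kw,
    ) -> "ClimbingDesign":
        """Success probability interpolated linearly between day endpoints."""
        days = tuple(int(d) for d in days)
        span = days[-1] - days[0]
        p = tuple(p_start + (p_end - p_start) * (d - days[0]) / span for d in days)
        return cls(days=days, p_success=p, **kw)


@dataclass(frozen=True)
class ScreenFixture:
    """A synthetic RNAi screen: genes with trajectories, GO terms, edges."""

    genes: tuple[ScreenGene, ...]
    go_annotations: Mapping[str, frozenset[str]]
    edges: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        ids = {g.gene for g in self.genes}
        if not set(self.go_annotations) <= ids:
            raise ValueError("annotated genes must appear in the gene list")


@dataclass(frozen=True)
class SyntheticImage:
    """A 2-D synthetic fibril field with its generating truth attached."""

    image: np.ndarray
    truth: StriationTruth
    pixel_size: float
    orientation: float
    fibril_rows: tuple[tuple[int, int], ...]  # (row_start, row_stop) pre-rotation
    template_profile: IntensityProfile = field(compare=False)


# ---------------------------------------------------------------------------
# striation profiles


def _striation_template(
    truth: StriationTruth, n_sarcomeres: int, peak_positions: np.ndarray, base_levels: bool
) -> tuple[np.ndarray, np.ndarray, float]:
    """Shared scaffolding: pixel grid, piecewise base + Gaussian peaks."""
    px = truth.pixel_size
    sl = truth.sarcomere_length
    margin = math.ceil((sl / 2.0) / px) * px
    total = 2.0 * margin + n_sarcomeres * sl
    n_px = int(round(total / px)) + 1
    pos = np.arange(n_px) * px

    rel = pos - margin
    if base_levels:
        # the fibril extends beyond the sampled window: the periodic
        # plateau/trough pattern continues through the margins so edge
        # sarcomeres see the same surroundings as interior ones
        base = np.full(n_px, truth.filament_level)
        if truth.h_zone_width > 0:
            phase = np.mod(rel, sl)
            in_h = np.abs(phase - sl / 2.0) <= truth.h_zone_width / 2.0
            base[in_h] = truth.h_zone_level
    else:
        base = np.full(n_px, truth.background)

    sigma_z = truth.z_disc_width / _FWHM
    amp = truth.z_peak_level - (truth.filament_level if base_levels else truth.background)
    centers = margin + peak_positions
    base = base + amp * np.exp(
        -0.5 * ((pos[:, None] - centers[None, :]) / sigma_z) ** 2
    ).sum(axis=1)
    return pos, base, margin


def _finish_profile(
    truth: StriationTruth,
    pos: np.ndarray,
    base: np.ndarray,
    noise_sd: float,
    seed: int,
    channel: str,
) -> IntensityProfile:
    out = base
    if truth.psf_sigma > 0:
        out = ndimage.gaussian_filter1d(out, truth.psf_sigma / truth.pixel_size, mode="nearest")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, out.size)
    out = np.maximum(out, 0.0)  # a detector never reports negative counts
    return IntensityProfile(pos, out, pixel_size=truth.pixel_size, channel=channel, truth=truth)


def _check_profile_args(truth: StriationTruth, n_sarcomeres: int, noise_sd: float) -> None:
    if n_sarcomeres < 2:
        raise ValueError("n_sarcomeres must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if truth.h_zone_width > 0 and truth.pixel_size >= truth.h_zone_width:
        raise ValueError("pixel_size >= h_zone_width: H-zone trough is unresolvable")


def gen_striation_profile(
    truth: StriationTruth, n_sarcomeres: int, noise_sd: float = 0.0, seed: int = 0
) -> IntensityProfile:
    """Phalloidin-channel striation profile: Z-disc peaks, plateau, H-zone.

    The continuous template places a Gaussian Z-disc peak at each period
    boundary, the thin-filament plateau over each filament array, and an
    ``h_zone_level`` trough of width ``h_zone_width`` centred mid-period;
    it is blurred by the Gaussian PSF, sampled at ``pixel_size``, and
    Gaussian noise of ``noise_sd`` is added.  The truth record is attached
    to the returned profile.
    """
    _check_profile_args(truth, n_sarcomeres, noise_sd)
    # flanking off-window peaks keep the edge Z-discs symmetric
    z_pos = np.arange(-1, n_sarcomeres + 2) * truth.sarcomere_length
    pos, base, _ = _striation_template(truth, n_sarcomeres, z_pos, base_levels=True)
    return _finish_profile(truth, pos, base, noise_sd, seed, "phalloidin")


def gen_mline_profile(
    truth: StriationTruth, n_sarcomeres: int, noise_sd: float = 0.0, seed: int = 0
) -> IntensityProfile:
    """Obscurin-channel profile: peaks at mid-period (M-line) positions only.

    Peaks are offset from the phalloidin Z-disc peaks by half a sarcomere;
    calibration (pixel grid, margins) matches :func:`gen_striation_profile`.
    """
    _check_profile_args(truth, n_sarcomeres, noise_sd)
    m_pos = (np.arange(n_sarcomeres) + 0.5) * truth.sarcomere_length
    pos, base, _ = _striation_template(truth, n_sarcomeres, m_pos, base_levels=False)
    return _finish_profile(truth, pos, base, noise_sd, seed, "obscurin")


def gen_striation_image(
    truth: StriationTruth,
    fibril_count: int = 3,
    fibril_width_px: int = 6,
    orientation: float = 0.0,
    seed: int = 0,
    n_sarcomeres: int = 6,
    noise_sd: float = 0.0,
    gap_px: int | None = None,
) -> SyntheticImage:
    """2-D field of parallel striped fibrils.

    At ``orientation=0`` the fibril axis runs along image columns, so a
    horizontal line profile through a fibril equals the 1-D generator
    output.  Right-angle orientations use exact array rotation; other
    angles use bilinear resampling.
    """
    if fibril_count < 1:
        raise ValueError("fibril_count must be >= 1")
    if fibril_width_px < 1 or n_sarcomeres < 1:
        raise ValueError("zero-area geometry")
    _check_profile_args(truth, max(n_sarcomeres, 2), noise_sd)

    template = gen_striation_profile(truth, max(n_sarcomeres, 2), noise_sd=0.0, seed=seed)
    row = template.intensities
    gap = fibril_width_px if gap_px is None else int(gap_px)
    n_rows = fibril_count * fibril_width_px + (fibril_count + 1) * gap
    img = np.full((n_rows, row.size), truth.background)
    fibril_rows = []
    for i in range(fibril_count):
        r0 = gap + i * (fibril_width_px + gap)
        img[r0 : r0 + fibril_width_px, :] = row[None, :]
        fibril_rows.append((r0, r0 + fibril_width_px))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.maximum(img, 0.0)

    angle = float(orientation) % 360.0
    if angle:
        if angle % 90.0 == 0.0:
            img = np.rot90(img, k=int(angle // 90))
        else:
            img = ndimage.rotate(img, angle, reshape=True, order=1, cval=truth.background)
    return SyntheticImage(
        image=img,
        truth=truth,
        pixel_size=truth.pixel_size,
        orientation=angle,
        fibril_rows=tuple(fibril_rows),
        template_profile=template,
    )


# ---------------------------------------------------------------------------
# pulse-chase


def gen_pulse_chase(
    kin: TurnoverKinetics,
    timepoints: Sequence[float],
    n_sarcomeres_per_tp: int = 40,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "Act88F_GFP",
) -> PulseChaseSeries:
    """Per-timepoint samples of Z-disc and sarcomere-body intensity.

    The noise-free Z-disc signal follows :meth:`TurnoverKinetics.mean_z`;
    body intensity is ``body_fraction`` of it.  Each of the
    ``n_sarcomeres_per_tp`` samples per timepoint gets independent additive
    Gaussian noise.
    """
    t = np.asarray(timepoints, dtype=float)
    if t.size == 0:
        raise ValueError("timepoints must not be empty")
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("timepoints must be non-negative and sorted")
    if n_sarcomeres_per_tp < 1:
        raise ValueError("n_sarcomeres_per_tp must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    z_samples, body_samples = [], []
    for ti in t:
        mu = kin.mean_z(float(ti))
        z = mu + rng.normal(0.0, noise_sd, n_sarcomeres_per_tp)
        body = kin.body_fraction * mu + rng.normal(0.0, noise_sd, n_sarcomeres_per_tp)
        z_samples.append(np.maximum(z, 0.0))
        body_samples.append(np.maximum(body, 0.0))
    return PulseChaseSeries(
        timepoints=t, z_intensity=z_samples, body_intensity=body_samples, label=label, truth=kin
    )


# ---------------------------------------------------------------------------
# qPCR


def gen_ct_table(design: QpcrDesign, n_replicates: int = 3, seed: int = 0):
    """Ct table under the doubling model.

    ``Ct = base_ct(gene) − log2(expression) + Normal(0, replicate_sd)``;
    the reference gene has expression 1 everywhere, so its Ct is constant
    in expectation.  Returns a tidy DataFrame with columns ``sample_id,
    genotype, day, gene, replicate, ct``.
    """
    import pandas as pd

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, day in design.conditions:
        sample_id = f"{genotype}_d{day}"
        for gene in (*design.targets, design.reference):
            expr = (
                1.0
                if gene == design.reference
                else float(design.expression[(gene, genotype, day)])
            )
            mu = design.base_ct[gene] - math.log2(expr)
            for rep in range(n_replicates):
                ct = mu + rng.normal(0.0, design.replicate_sd)
                rows.append(
                    {
                        "sample_id": sample_id,
                        "genotype": genotype,
                        "day": day,
                        "gene": gene,
                        "replicate": rep,
                        "ct": ct,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geotaxis


def gen_geotaxis(design: ClimbingDesign, seed: int = 0):
    """Binomial climbing outcomes per (vial, day, technical replicate).

    Returns a tidy DataFrame with columns ``line, vial, day, rep,
    successes, n_flies``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for day, p in zip(design.days, design.p_success):
        for vial in range(design.n_vials):
            for rep in range(design.tech_reps):
                rows.append(
                    {
                        "line": design.line,
                        "vial": vial,
                        "day": day,
                        "rep": rep,
                        "successes": int(rng.binomial(design.flies_per_vial, p)),
                        "n_flies": design.flies_per_vial,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# screen fixture

#: term -> (probability for hit genes, probability for 'None' genes)
DEFAULT_GO_VOCABULARY: dict[str, tuple[float, float]] = {
    "sarcomere": (0.65, 0.10),
    "actin cytoskeleton": (0.50, 0.15),
    "myosin complex": (0.35, 0.08),
    "integrin complex": (0.20, 0.05),
    "microtubule": (0.05, 0.25),
    "mitochondrion": (0.10, 0.30),
    "intracellular": (0.40, 0.45),
}


def _loss_trajectory(days: Sequence[int], day_of_loss: int | None, rng) -> dict[int, float]:
    """Normalised climbing trajectory: 1 at day 0, 0 from day_of_loss on."""
    traj = {}
    for d in days:
        if day_of_loss is None:
            score = max(0.15, 1.0 - 0.5 * d / max(days))  # mild age-related decline
        elif d >= day_of_loss:
            score = 0.0
        else:
            score = max(0.0, 1.0 - d / day_of_loss)
        if d > 0 and score > 0:
            score = max(0.02, score + rng.normal(0.0, 0.03))
        traj[int(d)] = float(score) if d > 0 else 1.0
    return traj


def gen_screen_fixture(
    class_counts: Mapping[str, int] | Sequence[int],
    assay_days: Sequence[int] = DEFAULT_ASSAY_DAYS,
    seed: int = 0,
    go_vocabulary: Mapping[str, tuple[float, float]] = DEFAULT_GO_VOCABULARY,
    n_edges: int | None = None,
) -> ScreenFixture:
    """Screen fixture with class-structured days of loss.

    ``class_counts`` gives the number of genes per severity class, either
    as a mapping or as a ``(Severe, Intermediate, Weak, None)`` tuple.
    Each gene's day of loss is drawn uniformly from the assay-grid days
    inside its class window; ``None`` genes never reach zero.  GO terms are
    drawn per gene from ``go_vocabulary`` with hit/non-hit probabilities,
    and ``n_edges`` random interaction edges (default 2 per gene) connect
    the genes, occasionally reflexively.
    """
    if not isinstance(class_counts, Mapping):
        class_counts = dict(zip(SEVERITY_CLASSES, class_counts))
    unknown = set(class_counts) - set(SEVERITY_CLASSES)
    if unknown:
        raise ValueError(f"unknown severity classes: {sorted(unknown)}")
    days = tuple(int(d) for d in assay_days)
    rng = np.random.default_rng(seed)

    genes: list[ScreenGene] = []
    annotations: dict[str, frozenset[str]] = {}
    idx = 0
    for cls in SEVERITY_CLASSES:
        count = int(class_counts.get(cls, 0))
        window = severity_window_days(cls, days)
        if cls != "None" and count > 0 and not window:
            raise ValueError(f"no assay day falls inside the {cls!r} window")
        for _ in range(count):
            gene = f"gene{idx:03d}"
            idx += 1
            loss = None if cls == "None" else int(rng.choice(window))
            traj = _loss_trajectory(days, loss, rng)
            p_col = 1 if cls == "None" else 0
            terms = frozenset(
                term for term, probs in go_vocabulary.items() if rng.random() < probs[p_col]
            )
            genes.append(
                ScreenGene(
                    gene=gene,
                    trajectory=traj,
                    day_of_loss=loss,
                    severity=cls,
                    go_terms=terms,
                )
            )
            annotations[gene] = terms

    ids = [g.gene for g in genes]
    edges: list[tuple[str, str, str]] = []
    if ids:
        m = 2 * len(ids) if n_edges is None else int(n_edges)
        for _ in range(m):
            u = ids[int(rng.integers(len(ids)))]
            v = u if rng.random() < 0.05 else ids[int(rng.integers(len(ids)))]
            kind = "genetic" if rng.random() < 0.5 else "physical"
            edges.append((u, v, kind))
    return ScreenFixture(genes=tuple(genes), go_annotations=annotations, edges=tuple(edges))
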
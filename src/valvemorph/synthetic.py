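"""Synthetic valves, striated textures, vote tables, and full cohorts.

The generator emulates the study conditions of a three-species Southern
Ocean *Fragilariopsis* comparison: closed valve outlines with controllable
length, width, heteropolarity, and central expansion; striated valve
textures with controllable stria period and orientation; and
multi-participant vote tables with experienced/novice confusion structure.
All randomness flows through an explicitly seeded generator per call.

Valve half-width profile on t in [-1, 1] (t = 2x/L along the apical axis)::

    r(t) = (W/2) * [ (1 - t^2)^(1/(2 + h*t)) + B * (1 - t^2) * exp(-t^2 / (2*sigma_b^2)) ]

h = 0 and B = 0 gives an exact ellipse; h > 0 makes the +x apex the broader
one; the bulge term is multiplied by (1 - t^2) so r(+-1) = 0 and contours
close cleanly at the apices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.draw import polygon as draw_polygon

from .io import (
    MaskedValveImage,
    Participant,
    SPECIES,
    Unit,
    ValveOutline,
    VoteTable,
)

__all__ = [
    "SyntheticValveParams",
    "StriaTextureParams",
    "VoteSimulationSpec",
    "SpeciesCohortSpec",
    "CohortSpec",
    "generate_outline",
    "outline_asymmetry_oracle",
    "generate_striated_image",
    "generate_vote_table",
    "generate_cohort",
    "default_cohort_spec",
]


@dataclass
class SyntheticValveParams:
    """Shape parameters of one synthetic valve (lengths in um)."""

    length: float = 60.0
    width: float = 8.0
    h: float = 0.0  # heteropolarity dial, >= 0; broader apex at +x
    bulge: float = 0.0  # central-expansion amplitude, dimensionless
    sigma_b: float = 0.25  # bulge width on the t axis
    n_points: int = 60

    def validate(self) -> None:
        if not self.length > self.width > 0:
            raise ValueError(f"need length > width > 0, got L={self.length}, W={self.width}")
        if self.h < 0 or self.bulge < 0:
            raise ValueError("h and bulge must be >= 0")
        if self.n_points < 6 or self.n_points % 2:
            raise ValueError("n_points must be an even number >= 6")

    def half_width(self, t: np.ndarray) -> np.ndarray:
        """r(t) in um; defined on [-1, 1] with r(+-1) = 0."""
        t = np.asarray(t, dtype=float)
        base = np.zeros_like(t)
        interior = np.abs(t) < 1.0
        ti = t[interior]
        base[interior] = (1.0 - ti**2) ** (1.0 / (2.0 + self.h * ti))
        bulge = self.bulge * (1.0 - t**2) * np.exp(-(t**2) / (2.0 * self.sigma_b**2))
        return (self.width / 2.0) * (base + bulge)


def generate_outline(
    params: SyntheticValveParams, specimen_id: str = "synthetic"
) -> tuple[ValveOutline, dict]:
    """Sample a closed valve outline and its analytic ground truth.

    Points are sampled at angles phi_j = 2*pi*j/n (t = cos phi), giving
    n_points/2 per side and counterclockwise traversal starting at the +x
    apex. Ground truth includes the area asymmetry about the major-axis
    midpoint from dense numerical integration.
    """
    params.validate()
    phi = 2.0 * np.pi * np.arange(params.n_points) / params.n_points
    t = np.cos(phi)
    r = params.half_width(t)
    y = np.where(np.abs(np.sin(phi)) < 1e-12, 0.0, r * np.sign(np.sin(phi)))
    pts = np.column_stack([(params.length / 2.0) * t, y])
    truth = {
        "specimen_id": specimen_id,
        "length": params.length,
        "width_param": params.width,
        "width_max": 2.0 * _max_half_width(params),
        "h": params.h,
        "bulge": params.bulge,
        "heteropolarity_index": outline_asymmetry_oracle(params),
    }
    return ValveOutline(specimen_id, pts, unit=Unit.micrometer), truth


def _max_half_width(params: SyntheticValveParams, n: int = 4001) -> float:
    t = np.linspace(-1, 1, n)
    return float(params.half_width(t).max())


def outline_asymmetry_oracle(params: SyntheticValveParams, n_panels: int = 20000) -> float:
    """Area-asymmetry fraction about the major-axis midpoint, by dense integration.

    |A(x>0) - A(x<0)| / A_total on >= n_panels trapezoid panels. This is the
    ground truth the polygon-clipping heteropolarity index is checked against.
    """
    if n_panels % 2:
        n_panels += 1  # keep t = 0 on the grid so the split is exact
    t = np.linspace(-1.0, 1.0, n_panels + 1)
    w = params.half_width(t)  # full width is 2r, the factor cancels
    mid = n_panels // 2
    neg = np.trapezoid(w[: mid + 1], t[: mid + 1])
    pos = np.trapezoid(w[mid:], t[mid:])
    return float(abs(pos - neg) / (pos + neg))


@dataclass
class StriaTextureParams:
    """Striation texture: density in striae per 10 um, orientation in degrees
    from the transapical axis (i.e. the wavevector's angle off the apical axis)."""

    density: float = 7.0
    theta_deg: float = 0.0
    amplitude: float = 60.0
    noise_sd: float = 5.0
    pixel_scale: float = 9.8

    @property
    def period_px(self) -> float:
        return 10.0 * self.pixel_scale / self.density

    def validate(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if abs(self.theta_deg) >= 45:
            raise ValueError("|theta| must be < 45 degrees")
        if self.period_px < 3:
            raise ValueError(
                f"stria period {self.period_px:.2f} px < 3 px is unresolvable"
            )


def generate_striated_image(
    valve: SyntheticValveParams,
    texture: StriaTextureParams,
    seed: int,
    specimen_id: str = "synthetic",
    margin_px: int = 8,
) -> tuple[MaskedValveImage, dict]:
    """Render a masked valve raster with a cosine striation pattern.

    Inside the hard-rasterized outline polygon the intensity is
    ``128 + A*cos(2*pi*(x*cos(theta) + y*sin(theta))/p)`` plus Gaussian noise,
    clipped to [1, 255]; background pixels are exactly 0.
    """
    valve.validate()
    texture.validate()
    rng = np.random.default_rng(seed)
    scale = texture.pixel_scale
    outline, _ = generate_outline(valve, specimen_id)
    pts_px = outline.points * scale
    pts_px -= pts_px.min(axis=0)
    pts_px += margin_px
    h_px = int(np.ceil(pts_px[:, 1].max())) + margin_px + 1
    w_px = int(np.ceil(pts_px[:, 0].max())) + margin_px + 1
    mask = np.zeros((h_px, w_px), dtype=bool)
    rr, cc = draw_polygon(pts_px[:, 1], pts_px[:, 0], shape=mask.shape)
    mask[rr, cc] = True

    yy, xx = np.mgrid[0:h_px, 0:w_px]
    th = np.deg2rad(texture.theta_deg)
    phase = 2.0 * np.pi * (xx * np.cos(th) + yy * np.sin(th)) / texture.period_px
    tex = 128.0 + texture.amplitude * np.cos(phase)
    if texture.noise_sd > 0:
        tex = tex + rng.normal(0.0, texture.noise_sd, size=tex.shape)
    tex = np.clip(np.rint(tex), 1, 255).astype(np.uint8)
    img = np.where(mask, tex, 0).astype(np.uint8)
    truth = {
        "specimen_id": specimen_id,
        "period_px": texture.period_px,
        "stria_density": texture.density,
        "stria_orientation": abs(texture.theta_deg),
    }
    return MaskedValveImage(specimen_id, img, pixel_scale=scale), truth


@dataclass
class VoteSimulationSpec:
    """Multi-participant vote simulation with per-experience-group confusion.

    Each confusion row gives P(vote species j | true species i) for the three
    species in :data:`~valvemorph.io.SPECIES` order; with probability
    ``ambiguity`` the vote becomes "ambiguous" instead, and independently with
    probability ``missing`` no vote is recorded. Rows plus ambiguity must sum
    to 1.
    """

    n_specimens: int = 100
    priors: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    # defaults emulate a panel of 8 experienced + 4 novice diatomists whose
    # unanimity cascade resembles the study's (roughly a third of specimens
    # in full agreement, experienced agreeing more often than novices)
    confusion_experienced: np.ndarray = field(
        default_factory=lambda: np.eye(3) * 0.93 + (np.ones((3, 3)) - np.eye(3)) * 0.02
    )
    confusion_novice: np.ndarray = field(
        default_factory=lambda: np.eye(3) * 0.82 + (np.ones((3, 3)) - np.eye(3)) * 0.04
    )
    ambiguity_experienced: float = 0.03
    ambiguity_novice: float = 0.10
    missing_experienced: float = 0.03
    missing_novice: float = 0.12
    n_experienced: int = 8
    n_novice: int = 4

    def validate(self) -> None:
        pri = np.asarray(self.priors, dtype=float)
        if pri.sum() <= 0 or (pri < 0).any():
            raise ValueError("degenerate class priors")
        for conf, amb, mis in (
            (self.confusion_experienced, self.ambiguity_experienced, self.missing_experienced),
            (self.confusion_novice, self.ambiguity_novice, self.missing_novice),
        ):
            conf = np.asarray(conf, dtype=float)
            if conf.shape != (3, 3) or (conf < 0).any():
                raise ValueError("confusion matrix must be 3x3 nonnegative")
            if not np.allclose(conf.sum(axis=1) + amb, 1.0, atol=1e-9):
                raise ValueError("each confusion row plus ambiguity must sum to 1")
            if not 0 <= mis < 1:
                raise ValueError("missing probability must be in [0, 1)")


def generate_vote_table(
    spec: VoteSimulationSpec, seed: int, true_labels: list[str] | None = None
) -> tuple[VoteTable, list[str]]:
    """Simulate a vote table; returns (table, true species labels)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    pri = np.asarray(spec.priors, dtype=float)
    pri = pri / pri.sum()
    if true_labels is None:
        idx = rng.choice(3, size=spec.n_specimens, p=pri)
        true_labels = [SPECIES[i] for i in idx]
    else:
        idx = np.array([SPECIES.index(lbl) for lbl in true_labels])
    participants = [Participant(f"E{i+1}", "experienced") for i in range(spec.n_experienced)]
    participants += [Participant(f"N{i+1}", "novice") for i in range(spec.n_novice)]
    cols = {}
    for p in participants:
        if p.group == "experienced":
            conf, amb, mis = (
                np.asarray(spec.confusion_experienced, float),
                spec.ambiguity_experienced,
                spec.missing_experienced,
            )
        else:
            conf, amb, mis = (
                np.asarray(spec.confusion_novice, float),
                spec.ambiguity_novice,
                spec.missing_novice,
            )
        votes = []
        for true_i in idx:
            if rng.random() < mis:
                votes.append("missing")
                continue
            probs = np.append(conf[true_i], amb)
            choice = rng.choice(4, p=probs / probs.sum())
            votes.append("ambiguous" if choice == 3 else SPECIES[choice])
        cols[p.id] = votes
    ids = [f"SYN{i:06d}" for i in range(len(true_labels))]
    votes_df = pd.DataFrame(cols, index=ids)
    table = VoteTable(specimen_ids=ids, participants=participants, votes=votes_df)
    return table, list(true_labels)


@dataclass
class TruncNormal:
    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)


@dataclass
class SpeciesCohortSpec:
    """Per-species morphometric distributions (truncated normals)."""

    name: str
    n: int
    length: TruncNormal
    width: TruncNormal
    h: TruncNormal
    bulge: TruncNormal
    density: TruncNormal
    theta: TruncNormal


@dataclass
class CohortSpec:
    species: list[SpeciesCohortSpec]
    votes: VoteSimulationSpec = field(default_factory=VoteSimulationSpec)
    n_points: int = 60
    pixel_scale: float = 9.8
    texture_amplitude: float = 60.0
    texture_noise_sd: float = 5.0


def default_cohort_spec(
    n_per_species: tuple[int, int, int] = (293, 135, 67),
    noise_sd: float = 5.0,
) -> CohortSpec:
    """Study-condition cohort: species morphometric distributions follow the
    published per-species summaries (length/width/stria statistics; h chosen so
    the asymmetry index matches the published species means: the index is
    ~0.0710*h for this profile family).

    n defaults to the study's majority-vote group sizes
    (ritscheri 293, obliquecostata 135, sublinearis 67).
    """
    rit = SpeciesCohortSpec(
        name="ritscheri",
        n=n_per_species[0],
        length=TruncNormal(50.7, 12.9, 20.3, 93.7),
        width=TruncNormal(8.62, 0.88, 6.3, 11.3),
        h=TruncNormal(0.55, 0.21, 0.05, 1.25),
        bulge=TruncNormal(0.02, 0.015, 0.0, 0.08),
        density=TruncNormal(7.4, 1.1, 5.2, 10.4),
        theta=TruncNormal(1.8, 2.3, 0.0, 16.0),
    )
    obl = SpeciesCohortSpec(
        name="obliquecostata",
        n=n_per_species[1],
        length=TruncNormal(67.8, 16.8, 32.2, 120.5),
        width=TruncNormal(8.16, 0.96, 5.9, 10.7),
        h=TruncNormal(0.24, 0.20, 0.0, 1.12),
        bulge=TruncNormal(0.06, 0.02, 0.0, 0.12),
        density=TruncNormal(6.5, 1.0, 4.7, 9.6),
        theta=TruncNormal(6.1, 3.4, 0.3, 18.9),
    )
    sub = SpeciesCohortSpec(
        name="sublinearis",
        n=n_per_species[2],
        length=TruncNormal(51.4, 11.1, 30.7, 75.3),
        width=TruncNormal(6.21, 0.49, 5.1, 7.4),
        h=TruncNormal(0.11, 0.10, 0.0, 0.56),
        bulge=TruncNormal(0.01, 0.01, 0.0, 0.05),
        density=TruncNormal(8.2, 0.7, 6.0, 10.1),
        theta=TruncNormal(3.9, 3.2, 0.0, 16.7),
    )
    return CohortSpec(species=[rit, obl, sub], texture_noise_sd=noise_sd)


def generate_cohort(
    spec: CohortSpec, seed: int, render_images: bool = True
) -> dict:
    """Generate a full synthetic cohort with known ground truth.

    Returns a dict with keys ``outlines`` (list of ValveOutline), ``images``
    (list of MaskedValveImage, empty if render_images=False), ``truth``
    (DataFrame of ground-truth features incl. species), and ``votes``
    (VoteTable simulated from the true species labels).
    """
    if not spec.species:
        raise ValueError("empty species list")
    rng = np.random.default_rng(seed)
    outlines: list[ValveOutline] = []
    images: list[MaskedValveImage] = []
    rows: list[dict] = []
    counter = 0
    for sp in spec.species:
        if sp.n == 0:
            continue
        L = sp.length.sample(rng, sp.n)
        W = sp.width.sample(rng, sp.n)
        H = sp.h.sample(rng, sp.n)
        B = sp.bulge.sample(rng, sp.n)
        D = sp.density.sample(rng, sp.n)
        T = sp.theta.sample(rng, sp.n)
        # a valve must be longer than wide
        L = np.maximum(L, W * 1.5)
        for i in range(sp.n):
            sid = f"SYN{counter:06d}"
            counter += 1
            vp = SyntheticValveParams(
                length=float(L[i]), width=float(W[i]), h=float(H[i]),
                bulge=float(B[i]), n_points=spec.n_points,
            )
            outline, truth = generate_outline(vp, sid)
            outlines.append(outline)
            truth.update(
                species=sp.name,
                stria_density=float(D[i]),
                stria_orientation=abs(float(T[i])),
            )
            rows.append(truth)
            if render_images:
                tp = StriaTextureParams(
                    density=float(D[i]),
                    theta_deg=float(T[i]),
                    amplitude=spec.texture_amplitude,
                    noise_sd=spec.texture_noise_sd,
                    pixel_scale=spec.pixel_scale,
                )
                img, _ = generate_striated_image(
                    vp, tp, seed=int(rng.integers(2**31)), specimen_id=sid
                )
                images.append(img)
    truth_df = pd.DataFrame(rows)
    votes, _ = generate_vote_table(
        spec.votes, seed=int(rng.integers(2**31)), true_labels=truth_df["species"].tolist()
    )
    # vote-table specimen ids follow generation order, which matches truth_df
    votes.votes.index = truth_df["specimen_id"].tolist()
    votes.specimen_ids = truth_df["specimen_id"].tolist()
    return {"outlines": outlines, "images": images, "truth": truth_df, "votes": votes}
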
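"""Synthetic cohorts, connectomes and coupled oscillator time series.

The generators reproduce the statistical structure the CPM analysis
assumes: a bimodal integer score distribution (healthy controls near the
scale floor, patients well above it), connectomes in which a small
planted edge set carries a linear score signal plus Gaussian noise, and
alpha-band oscillator time series whose pairwise phase locking is
modulated by the standardized score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from plvcpm._edges import N_REGIONS_DEFAULT, n_edges, triu_indices, unvectorize
from plvcpm.connectivity import Connectome, RegionalTimeSeries
from plvcpm.cpm import SCALE_RANGES

#: Cohort score moments (Table-1-like bimodal mixture on the BDI scale).
HC_SCORE_MEAN, HC_SCORE_SD = 1.6, 0.75
MDD_SCORE_MEAN, MDD_SCORE_SD = 22.0, 2.7

#: Demographic defaults: P(gender == 1) and age moments in years.
GENDER_P_DEFAULT = 0.4
AGE_MEAN_DEFAULT, AGE_SD_DEFAULT = 19.0, 0.6


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: raw score on a named scale, group and covariates."""

    subject_id: str
    raw_score: float
    scale: str
    group: str
    age: float
    gender: int

    def __post_init__(self) -> None:
        if self.scale not in SCALE_RANGES:
            raise ValueError(f"unknown scale {self.scale!r}; known: {sorted(SCALE_RANGES)}")
        rng_max = SCALE_RANGES[self.scale]
        if not 0 <= self.raw_score <= rng_max:
            raise ValueError(
                f"score {self.raw_score} outside the {self.scale} range [0, {rng_max:.0f}]"
            )
        if self.group not in ("HC", "MDD"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.gender not in (0, 1):
            raise ValueError(f"gender must be coded 0/1, got {self.gender}")


@dataclass
class PlantedModel:
    """Planted edge-level score signal for connectome generation.

    Edge weight for subject with standardized score z:
    ``base + s(e) * effect_size * z + N(0, noise_sd)`` where s(e) is +1
    on positive edges, -1 on negative edges, 0 elsewhere; results are
    clipped to [0, 1].
    """

    n_regions: int = N_REGIONS_DEFAULT
    pos_edges: frozenset[int] = field(default_factory=frozenset)
    neg_edges: frozenset[int] = field(default_factory=frozenset)
    effect_size: float = 0.1
    noise_sd: float = 0.05
    base: float = 0.3

    def __post_init__(self) -> None:
        self.pos_edges = frozenset(int(e) for e in self.pos_edges)
        self.neg_edges = frozenset(int(e) for e in self.neg_edges)
        if self.pos_edges & self.neg_edges:
            raise ValueError("pos_edges and neg_edges must be disjoint")
        m = n_edges(self.n_regions)
        for e in self.pos_edges | self.neg_edges:
            if not 0 <= e < m:
                raise ValueError(f"edge index {e} out of range for {self.n_regions} regions")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.base <= 1:
            raise ValueError("base coupling must lie in [0, 1]")

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_regions)

    def signs(self) -> np.ndarray:
        """Length n_edges vector with +1 / -1 on planted edges, 0 elsewhere."""
        s = np.zeros(self.n_edges)
        s[sorted(self.pos_edges)] = 1.0
        s[sorted(self.neg_edges)] = -1.0
        return s

    @classmethod
    def random(
        cls,
        n_pos: int = 33,
        n_neg: int = 5,
        n_regions: int = N_REGIONS_DEFAULT,
        effect_size: float = 0.1,
        noise_sd: float = 0.05,
        base: float = 0.3,
        seed: int = 0,
    ) -> "PlantedModel":
        """Place planted edges uniformly at random without replacement."""
        rng = np.random.default_rng(seed)
        picked = rng.choice(n_edges(n_regions), size=n_pos + n_neg, replace=False)
        return cls(
            n_regions=n_regions,
            pos_edges=frozenset(picked[:n_pos].tolist()),
            neg_edges=frozenset(picked[n_pos:].tolist()),
            effect_size=effect_size,
            noise_sd=noise_sd,
            base=base,
        )


def gen_cohort(
    n_hc: int,
    n_mdd: int,
    scale: str = "BDI",
    seed: int = 0,
    hc_mean: float = HC_SCORE_MEAN,
    hc_sd: float = HC_SCORE_SD,
    mdd_mean: float = MDD_SCORE_MEAN,
    mdd_sd: float = MDD_SCORE_SD,
    gender_p: float = GENDER_P_DEFAULT,
    age_mean: float = AGE_MEAN_DEFAULT,
    age_sd: float = AGE_SD_DEFAULT,
) -> list[SubjectRecord]:
    """Draw a bimodal cohort of integer scores on the named scale.

    Group scores come from normals with the configured moments, clipped
    to the scale's range and rounded to integers (psychometric scores
    are integer-valued). A fixed seed fixes the full record stream.
    """
    if n_hc < 0 or n_mdd < 0:
        raise ValueError("cohort counts must be non-negative")
    if scale not in SCALE_RANGES:
        raise ValueError(f"unknown scale {scale!r}")
    rng = np.random.default_rng(seed)
    rng_max = SCALE_RANGES[scale]
    records: list[SubjectRecord] = []
    for group, n, mu, sd in (("HC", n_hc, hc_mean, hc_sd), ("MDD", n_mdd, mdd_mean, mdd_sd)):
        scores = np.round(np.clip(rng.normal(mu, sd, size=n), 0.0, rng_max))
        genders = rng.binomial(1, gender_p, size=n)
        ages = rng.normal(age_mean, age_sd, size=n)
        for k in range(n):
            records.append(
                SubjectRecord(
                    subject_id=f"{group.lower()}_{k:04d}",
                    raw_score=float(scores[k]),
                    scale=scale,
                    group=group,
                    age=float(ages[k]),
                    gender=int(genders[k]),
                )
            )
    return records


def cohort_z_scores(cohort: list[SubjectRecord]) -> np.ndarray:
    """Within-cohort standardized raw scores (sample mean/SD, ddof=1)."""
    raw = np.array([s.raw_score for s in cohort], dtype=float)
    sd = raw.std(ddof=1) if raw.size > 1 else 1.0
    if sd == 0:
        sd = 1.0
    return (raw - raw.mean()) / sd


def gen_connectomes(
    cohort: list[SubjectRecord],
    model: PlantedModel,
    seed: int = 0,
    band: str = "alpha",
) -> list[Connectome]:
    """Generate one planted-signal connectome per subject.

    Edge weights follow the planted model against the within-cohort
    standardized score, are clipped to [0, 1], symmetrized and given a
    zero diagonal.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    rng = np.random.default_rng(seed)
    z = cohort_z_scores(cohort)
    signs = model.signs()
    out = []
    for subj, zi in zip(cohort, z):
        edges = model.base + signs * model.effect_size * zi
        edges = edges + rng.normal(0.0, model.noise_sd, size=model.n_edges)
        edges = np.clip(edges, 0.0, 1.0)
        out.append(
            Connectome(unvectorize(edges, model.n_regions), band=band, subject_id=subj.subject_id)
        )
    return out


# ---------------------------------------------------------------------------
# coupled oscillator time series


def _phase_noise(
    rng: np.random.Generator, n: int, fs: float, sd: float, cutoff: float = 0.5
) -> np.ndarray:
    """Smooth stationary phase perturbation: low-passed noise with SD ``sd``.

    Keeping the perturbation slow (default 0.5 Hz cutoff) keeps the
    oscillation inside its band; keeping it stationary makes the PLV of
    a convex phase mixture approximately exp(-(1-w)^2 * sd^2),
    monotone in the mixing weight w.
    """
    from scipy.signal import butter, sosfiltfilt

    white = rng.normal(size=n)
    sos = butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    slow = sosfiltfilt(sos, white)
    s = slow.std()
    return slow * (sd / s) if s > 0 else slow


def region_mixing_weights(
    model: PlantedModel,
    z_score: float,
    mixing_base: float = 0.5,
) -> dict[int, float]:
    """Per-planted-edge phase mixing weight in [0, 1].

    Positive edges couple more strongly as the standardized score
    rises; negative edges less strongly.
    """
    weights: dict[int, float] = {}
    for e in model.pos_edges:
        weights[e] = float(np.clip(mixing_base + model.effect_size * z_score, 0.0, 1.0))
    for e in model.neg_edges:
        weights[e] = float(np.clip(mixing_base - model.effect_size * z_score, 0.0, 1.0))
    return weights


def coupled_pair(
    weight: float,
    fs: float = 250.0,
    duration: float = 40.0,
    f0: float = 10.0,
    phase_sd: float = 2.5,
    noise_amp: float = 0.1,
    seed: int = 0,
) -> RegionalTimeSeries:
    """Two oscillators sharing a common phase term with the given weight.

    At weight 1 the phases are identical (alpha-band PLV ~ 1); at
    weight 0 the phases are independent (PLV near the estimator's
    noise floor); in between PLV rises monotonically with the weight.
    """
    if not 0 <= weight <= 1:
        raise ValueError("mixing weight must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    common = _phase_noise(rng, n, fs, phase_sd)
    own = [_phase_noise(rng, n, fs, phase_sd) for _ in range(2)]
    data = np.empty((2, n))
    for r in range(2):
        phase = 2 * np.pi * f0 * t + weight * common + (1.0 - weight) * own[r]
        data[r] = np.cos(phase) + noise_amp * rng.normal(size=n)
    return RegionalTimeSeries(data, fs)


def gen_coupled_timeseries(
    subject: SubjectRecord,
    model: PlantedModel,
    fs: float = 250.0,
    n_epochs: int = 4,
    epoch_len: float = 40.0,
    z_score: float | None = None,
    mixing_base: float = 0.5,
    f0: float = 10.0,
    phase_sd: float = 2.5,
    noise_amp: float = 0.1,
    amplitude: float = 50.0,
    seed: int = 0,
) -> RegionalTimeSeries:
    """Alpha-band coupled oscillator recording for one subject.

    Each region carries a 10 Hz oscillation on a random-walk phase plus
    broadband noise; regions joined by a planted edge mix in a shared
    phase term whose weight rises (positive edges) or falls (negative
    edges) with the standardized score, so downstream PLV tracks the
    score. The returned recording spans ``n_epochs * epoch_len``
    seconds and is scaled to ``amplitude`` muV.
    """
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz, got {fs}")
    if fs < 2 * 45.0:
        raise ValueError("fs below twice the highest band edge (45 Hz)")
    if z_score is None:
        # standardize against the default bimodal mixture moments
        mix_mean = 0.5 * (HC_SCORE_MEAN + MDD_SCORE_MEAN)
        mix_sd = np.sqrt(
            0.5 * (HC_SCORE_SD**2 + MDD_SCORE_SD**2)
            + 0.25 * (MDD_SCORE_MEAN - HC_SCORE_MEAN) ** 2
        )
        z_score = (subject.raw_score - mix_mean) / mix_sd
    rng = np.random.default_rng(seed)
    n = int(round(n_epochs * epoch_len * fs))
    t = np.arange(n) / fs

    weights = region_mixing_weights(model, z_score, mixing_base)
    iu, ju = triu_indices(model.n_regions)
    edge_latents = {e: _phase_noise(rng, n, fs, phase_sd) for e in weights}
    own_latents = [_phase_noise(rng, n, fs, phase_sd) for _ in range(model.n_regions)]

    # region phase = convex mix of its own walk and incident planted-edge walks
    data = np.empty((model.n_regions, n))
    for r in range(model.n_regions):
        incident = [(e, w) for e, w in weights.items() if iu[e] == r or ju[e] == r]
        w_sum = sum(w for _, w in incident)
        mix = np.zeros(n)
        if w_sum >= 1.0:
            for e, w in incident:
                mix += (w / w_sum) * edge_latents[e]
        else:
            mix = (1.0 - w_sum) * own_latents[r]
            for e, w in incident:
                mix += w * edge_latents[e]
        phase = 2 * np.pi * f0 * t + mix
        data[r] = np.cos(phase) + noise_amp * rng.normal(size=n)
    data *= amplitude
    return RegionalTimeSeries(data, fs)
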
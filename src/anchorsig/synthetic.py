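"""Synthetic expression cohorts with planted co-expression structure.

A single-factor Gaussian model generates the correlation block the anchor
screen is designed to detect.  Per sample ``s`` a latent factor
``f_s ~ N(0, 1)`` is drawn; a module gene ``g`` in group ``G`` takes

    x_gs = mu + delta * 1[tumor] + beta_G * f_s + eps_gs,   eps ~ N(0, sigma^2)

so any two equal-loading module genes (and the anchor, which is itself a
module gene) have analytic pairwise correlation ``beta_G^2 / (beta_G^2 +
sigma^2)`` within group ``G``.  Anti-regulated genes (FBP1-like) carry
``-beta_G`` and ``-delta``; background genes are pure noise around ``mu``.
Tumor stage is an ordinal bin of the standardized anchor score plus noise,
and survival times are exponential with a log-hazard linear in that score —
so stage composition and prognosis both track the planted signature, with the
ground truth retained for recovery tests.

All randomness flows from a single integer seed; the expression, survival and
stage draws use separate child streams so each operation is individually
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .core_data import ExpressionCohort, ProbeAnnotation, SampleMetadata

STAGE_LABELS = ("I", "II", "III", "IV", "V", "VI")

MODULE_CATEGORY = "cell cycle"


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings; defaults are the reference study conditions.

    ``mu`` and ``delta`` are on the log2 intensity scale, so a module gene's
    tumor/control ratio of group means is ``(mu + delta) / mu`` (1.125 at the
    defaults, inside the 1.05–1.7 range typical of microarray tumor/control
    comparisons).  ``gamma`` is the log hazard increase per standard deviation
    of anchor expression; ``lambda0`` is the baseline monthly hazard.
    """

    n_tumor: int = 150
    n_control: int = 150
    n_module: int = 25
    n_background: int = 500
    rho_tumor: float = 0.75
    rho_control: float = 0.35
    delta: float = 1.0
    delta_spread: float = 0.4
    anti_gene_count: int = 3
    sigma: float = 1.0
    mu: float = 8.0
    annotation_purity: float = 0.7
    background_annotation_rate: float = 0.037
    lambda0: float = 0.02
    gamma: float = math.log(2.5)
    censor_max_months: float = 120.0
    n_stages: int = 3
    stage_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tumor, self.n_control, self.n_module) < 1:
            raise ValueError("n_tumor, n_control and n_module must be positive")
        if self.n_background < 0 or self.anti_gene_count < 0:
            raise ValueError("n_background and anti_gene_count must be non-negative")
        for name in ("rho_tumor", "rho_control"):
            rho = getattr(self, name)
            if not -1 < rho < 1:
                raise ValueError(f"{name} must lie in (-1, 1), got {rho}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.lambda0 < 0:
            raise ValueError("lambda0 must be non-negative")
        if self.censor_max_months <= 0:
            raise ValueError("censor_max_months must be positive")
        if self.n_stages < 2:
            raise ValueError("n_stages must be at least 2")
        if not 0 <= self.annotation_purity <= 1:
            raise ValueError("annotation_purity must be in [0, 1]")
        if not 0 <= self.background_annotation_rate <= 1:
            raise ValueError("background_annotation_rate must be in [0, 1]")
        if not 0 <= self.delta_spread < 1:
            raise ValueError("delta_spread must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Planted ground truth: who is in the module, with what loadings."""

    anchor_probe: str
    module_probes: list[str]
    anti_probes: list[str]
    background_probes: list[str]
    loading_tumor: dict[str, float]
    loading_control: dict[str, float]
    delta_per_probe: dict[str, float]
    hazard_gamma: float
    n_stages: int
    stage_noise_sd: float
    module_member: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.module_member:
            members = {self.anchor_probe, *self.module_probes}
            all_probes = (
                [self.anchor_probe]
                + self.module_probes
                + self.anti_probes
                + self.background_probes
            )
            self.module_member = {p: p in members for p in all_probes}


def solve_loading(rho: float, sigma: float = 1.0) -> float:
    """Factor loading giving analytic pairwise correlation ``rho``.

    For two genes ``x_i = mu_i + beta * f + eps_i`` with shared ``f ~ N(0,1)``
    and independent ``eps_i ~ N(0, sigma^2)``,
    ``corr(x_1, x_2) = beta^2 / (beta^2 + sigma^2)``; inverting gives
    ``beta = sigma * sqrt(rho / (1 - rho))``.
    """
    if not 0 <= rho < 1:
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return sigma * math.sqrt(rho / (1.0 - rho))


def _streams(seed: int) -> tuple[np.random.Generator, ...]:
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def simulate_expression(
    params: SyntheticParams,
) -> tuple[ExpressionCohort, list[SampleMetadata], dict[str, ProbeAnnotation], SyntheticTruth]:
    """Draw a cohort from the single-factor model, with annotations and truth.

    Deterministic under ``params.seed``.  Module genes (anchor included) are
    labeled with the module category with probability ``annotation_purity``;
    background genes with probability ``background_annotation_rate``,
    emulating a platform where only a few percent of probes carry the label.
    """
    rng, _, _ = _streams(params.seed)

    anchor = "ANCH0000_at"
    module = [f"MOD{i:04d}_at" for i in range(params.n_module)]
    anti = [f"ANTI{i:04d}_at" for i in range(params.anti_gene_count)]
    background = [f"BKG{i:04d}_at" for i in range(params.n_background)]
    probes = [anchor] + module + anti + background

    tumor_ids = [f"T{i:04d}" for i in range(params.n_tumor)]
    control_ids = [f"C{i:04d}" for i in range(params.n_control)]
    samples = tumor_ids + control_ids
    is_tumor = np.array([1.0] * params.n_tumor + [0.0] * params.n_control)

    beta_t = solve_loading(params.rho_tumor, params.sigma)
    beta_c = solve_loading(params.rho_control, params.sigma)
    # per-probe loading sign: +1 anchor/module, -1 anti, 0 background
    sign = np.array(
        [1.0] * (1 + params.n_module)
        + [-1.0] * params.anti_gene_count
        + [0.0] * params.n_background
    )
    # per-gene mean shifts: the anchor sits at delta exactly; module genes get
    # a symmetric even spread around delta (real modules show heterogeneous
    # fold changes); anti-genes are shifted down by delta
    if params.n_module > 1:
        spread = params.delta * (
            1.0
            + params.delta_spread * np.linspace(-1.0, 1.0, params.n_module)
        )
    else:
        spread = np.array([params.delta])
    delta_p = np.concatenate(
        [
            [params.delta],
            spread,
            np.full(params.anti_gene_count, -params.delta),
            np.zeros(params.n_background),
        ]
    )

    f = rng.standard_normal(len(samples))
    eps = rng.standard_normal((len(probes), len(samples))) * params.sigma
    beta_s = np.where(is_tumor == 1.0, beta_t, beta_c)  # per-sample group loading
    values = (
        params.mu
        + delta_p[:, None] * is_tumor[None, :]
        + sign[:, None] * beta_s[None, :] * f[None, :]
        + eps
    )
    cohort = ExpressionCohort(probes, samples, values)

    metadata = [
        SampleMetadata(sample_id=s, group="tumor", cohort_label="synthetic")
        for s in tumor_ids
    ] + [
        SampleMetadata(sample_id=s, group="control", cohort_label="synthetic")
        for s in control_ids
    ]

    annotation: dict[str, ProbeAnnotation] = {}
    annotation[anchor] = ProbeAnnotation(
        anchor, "ANCHOR", "synthetic anchor gene", frozenset({"glycolysis"})
    )
    for i, p in enumerate(module):
        cats = {MODULE_CATEGORY} if rng.random() < params.annotation_purity else set()
        annotation[p] = ProbeAnnotation(p, f"MOD{i}", "synthetic module gene", frozenset(cats))
    for i, p in enumerate(anti):
        annotation[p] = ProbeAnnotation(
            p, f"ANTI{i}", "synthetic anti-regulated gene", frozenset({"gluconeogenesis"})
        )
    for i, p in enumerate(background):
        cats = {MODULE_CATEGORY} if rng.random() < params.background_annotation_rate else set()
        annotation[p] = ProbeAnnotation(p, f"BKG{i}", "synthetic background gene", frozenset(cats))

    truth = SyntheticTruth(
        anchor_probe=anchor,
        module_probes=module,
        anti_probes=anti,
        background_probes=background,
        loading_tumor={p: sign[i] * beta_t for i, p in enumerate(probes)},
        loading_control={p: sign[i] * beta_c for i, p in enumerate(probes)},
        delta_per_probe={p: delta_p[i] for i, p in enumerate(probes)},
        hazard_gamma=params.gamma,
        n_stages=params.n_stages,
        stage_noise_sd=params.stage_noise_sd,
    )
    return cohort, metadata, annotation, truth


def _tumor_anchor_z(
    cohort: ExpressionCohort, truth: SyntheticTruth, metadata: list[SampleMetadata]
) -> tuple[list[str], np.ndarray]:
    tumor_ids = [m.sample_id for m in metadata if m.group == "tumor"]
    if not tumor_ids:
        raise ValueError("no tumor samples to simulate outcomes for")
    idx = cohort.sample_index
    x = cohort.probe_values(truth.anchor_probe)[[idx[s] for s in tumor_ids]]
    sd = x.std(ddof=0)
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    return tumor_ids, z


def simulate_survival(
    cohort: ExpressionCohort,
    truth: SyntheticTruth,
    params: SyntheticParams,
    metadata: list[SampleMetadata],
) -> list[SampleMetadata]:
    """Attach exponential survival outcomes to the tumor samples.

    Event times are Exponential with rate ``lambda0 * exp(gamma * z_s)``
    where ``z_s`` is the standardized anchor expression among tumors;
    administrative censoring is Uniform(0, censor_max_months).  Months are
    reported at 0.1 resolution.  Control samples keep no survival data.
    """
    _, rng, _ = _streams(params.seed)
    tumor_ids, z = _tumor_anchor_z(cohort, truth, metadata)
    rate = params.lambda0 * np.exp(params.gamma * z)
    with np.errstate(divide="ignore"):
        scale = np.where(rate > 0, 1.0 / rate, np.inf)
    t_event = rng.exponential(1.0, size=len(tumor_ids)) * scale
    t_censor = rng.uniform(0.0, params.censor_max_months, size=len(tumor_ids))
    months = np.round(np.minimum(t_event, t_censor), 1)
    event = (t_event <= t_censor).astype(int)

    by_id = dict(zip(tumor_ids, range(len(tumor_ids))))
    out: list[SampleMetadata] = []
    for m in metadata:
        if m.sample_id in by_id:
            i = by_id[m.sample_id]
            out.append(
                SampleMetadata(
                    sample_id=m.sample_id,
                    group=m.group,
                    cohort_label=m.cohort_label,
                    stage=m.stage,
                    survival_months=float(months[i]),
                    event=int(event[i]),
                )
            )
        else:
            out.append(m)
    return out


def simulate_stages(
    cohort: ExpressionCohort,
    truth: SyntheticTruth,
    params: SyntheticParams,
    metadata: list[SampleMetadata],
) -> list[SampleMetadata]:
    """Assign ordinal stage labels to tumor samples.

    Stage is the equal-frequency quantile bin of ``z_s + noise`` with noise sd
    ``stage_noise_sd``, so mean signature expression increases with stage in
    expectation; with zero noise the binning is a deterministic function of
    the anchor score.
    """
    _, _, rng = _streams(params.seed)
    tumor_ids, z = _tumor_anchor_z(cohort, truth, metadata)
    score = z + params.stage_noise_sd * rng.standard_normal(len(tumor_ids))
    edges = np.quantile(score, np.linspace(0, 1, params.n_stages + 1)[1:-1])
    bins = np.searchsorted(edges, score, side="right")
    labels = {s: STAGE_LABELS[b] for s, b in zip(tumor_ids, bins)}

    out: list[SampleMetadata] = []
    for m in metadata:
        if m.sample_id in labels:
            out.append(
                SampleMetadata(
                    sample_id=m.sample_id,
                    group=m.group,
                    cohort_label=m.cohort_label,
                    stage=labels[m.sample_id],
                    survival_months=m.survival_months,
                    event=m.event,
                )
            )
        else:
            out.append(m)
    return out


def simulate_cohort(
    params: SyntheticParams,
) -> tuple[ExpressionCohort, list[SampleMetadata], dict[str, ProbeAnnotation], SyntheticTruth]:
    """Full generator: expression + stages + survival in one call."""
    cohort, metadata, annotation, truth = simulate_expression(params)
    metadata = simulate_stages(cohort, truth, params, metadata)
    metadata = simulate_survival(cohort, truth, params, metadata)
    return cohort, metadata, annotation, truth
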
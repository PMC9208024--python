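"""Synthetic cohorts with planted structure-function coupling.

Generates healthy-control (HC), cognitively-preserved (CP) and
cognitively-impaired (CI) subjects whose structural connectomes,
narrowband source time series and cognitive z-scores carry the
statistical structure the downstream analysis assumes:

* a shared tract-length template with a right-skewed distribution, so
  group-level quartile thresholds are meaningful across subjects;
* FA that decreases with tract length, with an optional long-range
  deficit for CI subjects;
* per-edge target envelope correlations that are a monotone (affine)
  function of FA on structurally present edges, with a group-specific
  slope — the planted coupling effect;
* a negative between-subject association between a subject's overall
  FA level and overall FC level, so group-level SC-FC correlations are
  detectable at desk scale;
* cognitive z-scores that reproduce each subject's group label under
  the impairment rule (z <= -2 on at least two domains for CI).

Cohorts can be realized either as full narrowband time series (the
signals' estimated envelope correlations are then monotone in the
planted targets) or directly as FC matrices (an idealized estimator:
the planted correlation is taken as the AECc), which is orders of
magnitude faster and is what the calibration studies use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .fc import (
    DEFAULT_BANDS,
    FCMatrix,
    FrequencyBand,
    SourceTimeSeries,
)
from .sc import StructuralConnectome
from .stats import COGNITIVE_DOMAINS, classify_cognitive_status

__all__ = [
    "CohortConfig",
    "Subject",
    "CohortRecord",
    "Cohort",
    "generate_tract_lengths",
    "generate_structural_connectome",
    "generate_envelope_correlated_series",
    "generate_cohort",
    "nearest_correlation_psd",
]

GROUPS = ("HC", "CP", "CI")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Group sizes default to the study layout (40 HC, 46 CP, 33 CI) over
    78 cortical nodes with 13 epochs of 16,384 samples at 1250 Hz.
    ``coupling_slope_by_group`` sets the slope of the planted envelope-
    correlation target versus FA per group — the within-subject coupling
    effect; ``fa_group_deficit_long`` lowers long-range FA in CI.
    """

    n_hc: int = 40
    n_cp: int = 46
    n_ci: int = 33
    n_nodes: int = 78
    sampling_rate: float = 1250.0
    n_epochs: int = 13
    epoch_samples: int = 16384
    length_range: tuple[float, float] = (10.0, 250.0)
    length_jitter_sd: float = 2.0  # mm, per-subject deviation from the template
    fa_base: float = 0.50
    fa_length_slope: float = 3.0e-4  # FA decrease per mm of tract length
    fa_noise_sd: float = 0.02
    fa_group_deficit_long: float = 0.03  # CI-specific FA decrement on long edges
    fa_subject_sd: float = 0.012  # per-subject global FA offset
    absent_fraction: float = 0.15  # fraction of edges with no tract
    coupling_slope_by_group: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.2, "CP": 0.35, "CI": 0.9}
    )
    fc_base: float = 0.25  # baseline target envelope correlation on edges
    fc_subject_slope: float = -1.2  # FC level change per unit subject FA offset
    fc_subject_sd: float = 0.012  # per-subject FC level noise
    noise_sd: float = 0.05  # per-edge noise on the planted envelope correlation
    planted_band: FrequencyBand = DEFAULT_BANDS[0]  # theta carries the coupling
    env_bandwidth: float = 1.0  # Hz, bandwidth of latent envelope drivers
    mod_depth: float = 0.4  # amplitude-modulation depth of the carriers
    carrier_noise_sd: float = 0.05  # broadband additive noise on the signals
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hc", "n_cp", "n_ci", "n_nodes", "n_epochs", "epoch_samples"):
            if getattr(self, name) < 0 or (name not in ("n_hc", "n_cp", "n_ci") and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be at least 2")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lo, hi = self.length_range
        if not (0 < lo < hi):
            raise ValueError(f"invalid length_range {self.length_range}: need 0 < low < high")
        if not 0 <= self.absent_fraction <= 1:
            raise ValueError("absent_fraction must lie in [0, 1]")
        missing = set(GROUPS) - set(self.coupling_slope_by_group)
        if missing:
            raise ValueError(f"coupling_slope_by_group missing groups: {sorted(missing)}")

    @property
    def n_subjects(self) -> int:
        return self.n_hc + self.n_cp + self.n_ci

    @property
    def n_samples(self) -> int:
        return self.n_epochs * self.epoch_samples

    def node_labels(self) -> list[str]:
        return [f"node{i:03d}" for i in range(self.n_nodes)]


@dataclass
class Subject:
    """Demographics, covariates and cognitive profile of one participant."""

    id: str
    group: str
    age: float
    sex: int  # 1 = female, 0 = male
    education: str  # "low" | "high"
    domain_z: np.ndarray  # one z-score per cognitive domain

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        self.domain_z = np.asarray(self.domain_z, dtype=float)

    @property
    def is_patient(self) -> bool:
        return self.group in ("CP", "CI")


@dataclass
class CohortRecord:
    """One subject with their structural connectome and functional data.

    ``planted`` holds generator internals (target envelope correlations,
    the subject's FA offset and FC level, the coupling slope used) so
    that recovery tests can compare estimates against the ground truth.
    """

    subject: Subject
    connectome: StructuralConnectome
    timeseries: SourceTimeSeries | None = None
    fc: dict[str, FCMatrix] = field(default_factory=dict)
    planted: dict = field(default_factory=dict)


@dataclass
class Cohort:
    config: CohortConfig
    records: list[CohortRecord]
    length_template: np.ndarray | None = None

    def by_group(self, group: str) -> list[CohortRecord]:
        return [r for r in self.records if r.subject.group == group]

    @property
    def subjects(self) -> list[Subject]:
        return [r.subject for r in self.records]


# ---------------------------------------------------------------------------
# tract lengths


def generate_tract_lengths(
    config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Shared tract-length template (mm), symmetric with zero diagonal.

    Off-diagonal lengths follow a right-skewed unimodal distribution on
    ``length_range``: a Beta(2, 4) draw linearly mapped onto the range,
    i.e. a gamma-like shape with bounded support.  The template is
    shared across subjects (up to per-subject jitter applied by the
    cohort generator) so that pooled quartile thresholds are meaningful.
    """
    n = config.n_nodes
    lo, hi = config.length_range
    iu = np.triu_indices(n, k=1)
    raw = rng.beta(2.0, 4.0, size=iu[0].size)
    lengths = lo + (hi - lo) * raw
    m = np.zeros((n, n))
    m[iu] = lengths
    return m + m.T


def _jitter_lengths(
    template: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    n = template.shape[0]
    iu = np.triu_indices(n, k=1)
    jit = rng.normal(0.0, config.length_jitter_sd, size=iu[0].size)
    vals = np.clip(template[iu] + jit, *config.length_range)
    m = np.zeros_like(template)
    m[iu] = vals
    return m + m.T


# ---------------------------------------------------------------------------
# structural connectomes


def generate_structural_connectome(
    lengths: np.ndarray,
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    subject_offset: float = 0.0,
) -> np.ndarray:
    """FA matrix for one subject: longer tracts carry lower FA.

    FA = fa_base + subject_offset - fa_length_slope * length, minus
    ``fa_group_deficit_long`` on long-range edges (above the 75th
    percentile of this subject's tract lengths) for CI subjects, plus
    Gaussian noise; entries are clipped to [0, 1] and a random
    ``absent_fraction`` of edges is set to exactly zero (absent tracts).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    n = lengths.shape[0]
    iu = np.triu_indices(n, k=1)
    edge_len = lengths[iu]
    fa = (
        config.fa_base
        + subject_offset
        - config.fa_length_slope * edge_len
        + rng.normal(0.0, config.fa_noise_sd, size=edge_len.size)
    )
    if group == "CI" and config.fa_group_deficit_long != 0.0:
        q3 = np.quantile(edge_len, 0.75)
        fa = fa - config.fa_group_deficit_long * (edge_len > q3)
    fa = np.clip(fa, 0.0, 1.0)
    if config.absent_fraction > 0.0:
        n_absent = int(round(config.absent_fraction * edge_len.size))
        absent = rng.choice(edge_len.size, size=n_absent, replace=False)
        fa[absent] = 0.0
    m = np.zeros_like(lengths)
    m[iu] = fa
    return m + m.T


# ---------------------------------------------------------------------------
# envelope-correlated time series


def nearest_correlation_psd(c: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalues are clipped at ``eps`` and the result is rescaled to a
    unit diagonal.  Used to repair small indefiniteness introduced by
    planting independent per-edge targets.
    """
    c = (c + c.T) / 2.0
    w, v = np.linalg.eigh(c)
    w = np.clip(w, eps, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _lowpass_drivers(
    n_channels: int,
    n_samples: int,
    sampling_rate: float,
    bandwidth: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Standardized slow Gaussian drivers (band-limited below ``bandwidth``)."""
    z = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(z, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    keep = (freqs > 0) & (freqs <= bandwidth)
    spec[:, ~keep] = 0.0
    drivers = np.fft.irfft(spec, n=n_samples, axis=-1)
    drivers -= drivers.mean(axis=1, keepdims=True)
    sd = drivers.std(axis=1, keepdims=True)
    sd[sd == 0.0] = 1.0
    return drivers / sd


def generate_envelope_correlated_series(
    target_env_corr: np.ndarray,
    band: FrequencyBand,
    config: CohortConfig,
    rng: np.random.Generator,
    return_envelopes: bool = False,
    label: str = "target_env_corr",
) -> SourceTimeSeries | tuple[SourceTimeSeries, np.ndarray]:
    """Narrowband signals whose envelope correlations follow a target.

    Latent slow Gaussian drivers are mixed through a symmetric matrix
    square root of ``target_env_corr``, shifted and rectified into
    non-negative envelopes, and used to amplitude-modulate independent
    band-limited noise carriers.  Estimated envelope correlations of the
    output are attenuated relative to the target (rectification and
    orthogonalization both shrink them) but monotone in it.
    """
    c = np.asarray(target_env_corr, dtype=float)
    n = c.shape[0]
    if c.ndim != 2 or c.shape != (n, n) or not np.allclose(c, c.T, atol=1e-10):
        raise ValueError(f"{label} must be a symmetric square matrix")
    if not np.allclose(np.diag(c), 1.0):
        raise ValueError(f"{label} must have a unit diagonal")
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    if w.min() < -1e-8:
        raise ValueError(
            f"{label} is not positive semidefinite (min eigenvalue {w.min():.3g})"
        )
    root = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T

    n_samples = config.n_samples
    drivers = _lowpass_drivers(
        n, n_samples, config.sampling_rate, config.env_bandwidth, rng
    )
    latent = root @ drivers
    envelopes = np.clip(1.0 + config.mod_depth * latent, 0.05, None)

    carrier_noise = rng.standard_normal((n, n_samples))
    spec = np.fft.rfft(carrier_noise, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / config.sampling_rate)
    keep = (freqs >= band.low) & (freqs < band.high)
    spec[:, ~keep] = 0.0
    carriers = np.fft.irfft(spec, n=n_samples, axis=-1)
    carriers /= carriers.std(axis=1, keepdims=True)

    data = envelopes * carriers
    if config.carrier_noise_sd > 0.0:
        data = data + config.carrier_noise_sd * rng.standard_normal((n, n_samples))
    ts = SourceTimeSeries(
        data=data,
        sampling_rate=config.sampling_rate,
        channel_labels=[f"node{i:03d}" for i in range(n)],
    )
    return (ts, envelopes) if return_envelopes else ts


# ---------------------------------------------------------------------------
# cognitive profiles


def _draw_domain_z(
    group: str, rng: np.random.Generator, threshold: float = -2.0, min_domains: int = 2
) -> np.ndarray:
    """Cognitive z-scores consistent with the group's impairment status."""
    k = len(COGNITIVE_DOMAINS)
    shift = {"HC": 0.0, "CP": -0.5, "CI": -1.0}[group]
    z = shift + rng.standard_normal(k)
    if group == "CI":
        n_impaired = min(k, 2 + rng.binomial(3, 0.4))
        which = rng.choice(k, size=n_impaired, replace=False)
        z[which] = threshold - np.abs(rng.normal(0.5, 0.4, size=n_impaired))
    else:
        # at most one domain may cross the impairment threshold
        low = np.flatnonzero(z <= threshold)
        for idx in low[1:] if low.size >= min_domains else []:
            while z[idx] <= threshold:
                z[idx] = shift + rng.standard_normal()
    return z


def _draw_demographics(
    group: str, rng: np.random.Generator
) -> tuple[float, int, str]:
    if group == "HC":
        age = rng.normal(50.7, 6.1)
        sex = int(rng.random() < 0.63)
        education = "high" if rng.random() < 0.60 else "low"
    else:
        age = rng.normal(53.8, 10.7)
        sex = int(rng.random() < 0.72)
        education = "high" if rng.random() < 0.50 else "low"
    return float(np.clip(age, 18.0, 90.0)), sex, education


# ---------------------------------------------------------------------------
# full cohort


def _planted_edge_correlations(
    fa_edges: np.ndarray,
    present: np.ndarray,
    slope: float,
    fc_level: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Target envelope correlation per edge: affine in FA where present."""
    fa_ref = config.fa_base - config.fa_length_slope * np.mean(config.length_range)
    target = np.full(fa_edges.shape, config.fc_base + fc_level)
    target[present] += slope * (fa_edges[present] - fa_ref)
    if config.noise_sd > 0.0:
        target = target + rng.normal(0.0, config.noise_sd, size=target.shape)
    return np.clip(target, 0.0, 0.9)


def generate_cohort(
    config: CohortConfig,
    mode: str = "timeseries",
) -> Cohort:
    """Generate a full synthetic cohort.

    ``mode='timeseries'`` synthesizes narrowband signals per subject in
    the planted band (the AECc must then be estimated from them);
    ``mode='fc'`` instead emits FC matrices directly, taking the planted
    envelope correlation as the estimate for the planted band and a null
    (zero-correlation) value for the other bands — the fast path used by
    replicated calibration studies; ``mode='both'`` emits both.
    """
    if mode not in ("timeseries", "fc", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    for name, n in (("n_hc", config.n_hc), ("n_cp", config.n_cp), ("n_ci", config.n_ci)):
        if n == 0:
            warnings.warn(
                f"{name} is 0: downstream group contrasts involving that group "
                "will be undefined",
                RuntimeWarning,
                stacklevel=2,
            )
    root_rng = np.random.default_rng(config.seed)
    template = generate_tract_lengths(config, root_rng)
    labels = config.node_labels()
    iu = np.triu_indices(config.n_nodes, k=1)

    groups = ["HC"] * config.n_hc + ["CP"] * config.n_cp + ["CI"] * config.n_ci
    records: list[CohortRecord] = []
    subject_rngs = root_rng.spawn(len(groups))
    for idx, (group, rng) in enumerate(zip(groups, subject_rngs)):
        sid = f"sub{idx:03d}"
        age, sex, education = _draw_demographics(group, rng)
        domain_z = _draw_domain_z(group, rng)
        if group != "HC":
            assigned = classify_cognitive_status(domain_z)
            if assigned != group:  # defensive; construction should guarantee this
                raise RuntimeError(
                    f"generated z-scores of {sid} classify as {assigned}, not {group}"
                )
        subject = Subject(sid, group, age, sex, education, domain_z)

        lengths = _jitter_lengths(template, config, rng)
        delta = rng.normal(0.0, config.fa_subject_sd)
        fa = generate_structural_connectome(
            lengths, group, config, rng, subject_offset=delta
        )
        connectome = StructuralConnectome(fa=fa, lengths=lengths, node_labels=labels)

        slope = config.coupling_slope_by_group[group]
        fc_level = config.fc_subject_slope * delta + rng.normal(
            0.0, config.fc_subject_sd
        )
        present = fa[iu] > 0
        target_edges = _planted_edge_correlations(
            fa[iu], present, slope, fc_level, config, rng
        )
        target = np.eye(config.n_nodes)
        target[iu] = target_edges
        target = target + target.T - np.diag(np.diag(target))
        np.fill_diagonal(target, 1.0)

        planted = {
            "target_env_corr": target,
            "coupling_slope": slope,
            "fa_offset": delta,
            "fc_level": fc_level,
        }
        record = CohortRecord(
            subject=subject, connectome=connectome, planted=planted
        )
        if mode in ("timeseries", "both"):
            psd_target = nearest_correlation_psd(target)
            planted["target_env_corr_psd"] = psd_target
            ts, env = generate_envelope_correlated_series(
                psd_target,
                config.planted_band,
                config,
                rng,
                return_envelopes=True,
                label=f"target_env_corr[{sid}]",
            )
            ts.channel_labels = list(labels)
            planted["latent_envelopes"] = env
            record.timeseries = ts
        if mode in ("fc", "both"):
            record.fc = _direct_fc(target_edges, config, labels, rng)
        records.append(record)
    return Cohort(config=config, records=records, length_template=template)


def _direct_fc(
    target_edges: np.ndarray,
    config: CohortConfig,
    labels: list[str],
    rng: np.random.Generator,
) -> dict[str, FCMatrix]:
    """Idealized FC matrices: planted correlation taken as the AECc."""
    n = config.n_nodes
    iu = np.triu_indices(n, k=1)
    out: dict[str, FCMatrix] = {}
    for band in DEFAULT_BANDS:
        if band.name == config.planted_band.name:
            aecc = target_edges
        else:
            # null band: only estimation noise around zero correlation
            aecc = rng.normal(0.0, config.noise_sd, size=target_edges.shape)
        m = np.zeros((n, n))
        m[iu] = (np.clip(aecc, -1.0, 1.0) + 1.0) / 2.0
        m = m + m.T
        out[band.name] = FCMatrix(
            values=m, band=band, rescaled=True, node_labels=list(labels)
        )
    return out


def config_to_dict(config: CohortConfig) -> dict:
    """Plain-dict snapshot of a cohort config (for YAML provenance)."""
    d = asdict(config)
    d["length_range"] = list(config.length_range)
    d["planted_band"] = {
        "name": config.planted_band.name,
        "low": config.planted_band.low,
        "high": config.planted_band.high,
    }
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "length_range" in d:
        d["length_range"] = tuple(d["length_range"])
    pb = d.get("planted_band")
    if isinstance(pb, dict):
        d["planted_band"] = FrequencyBand(pb["name"], pb["low"], pb["high"])
    return CohortConfig(**d)
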
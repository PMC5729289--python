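"""Synthetic cohorts with planted modular and treatment-interaction structure.

The generator emulates the statistical skeleton of a two-cohort
chemotherapy-benefit study: a sparse protein network with planted dense
modules, expression in which each planted module's genes share a latent
per-sample factor plus Gaussian noise, a latent two-class patient subtype
that shifts the factors of a subset of "predictive" modules, Bernoulli
treatment assignment, and proportional-hazards survival times whose
treatment effect reverses between subtypes.  Training and validation
cohorts are independent sample draws from one generative truth, so every
pipeline stage can be exercised — and its recovery of the planted truth
measured — without any external download.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import PPINetwork, write_edgelist
from .prep import ClinicalTable, DetectionMatrix, ExpressionMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "CohortBundle",
    "generate_network",
    "generate_expression",
    "generate_clinical",
    "generate_cohorts",
    "generate_screen_scenario",
    "write_scenario",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative truth parameters for one simulated study.

    Defaults describe a desk-scale two-cohort design: 60 planted modules
    (6 of them treatment-predictive) among 1200 network nodes, 300 training
    and 150 validation patients, balanced treatment assignment, and a
    treatment effect that reverses between the two latent subtypes
    (hazard ratio 0.5 in subtype 1 vs 2.0 in subtype 2).
    """

    n_modules: int = 60
    module_size_range: tuple[int, int] = (5, 15)
    n_background_nodes: int = 600
    p_in: float = 0.9
    p_out: float = 0.001
    n_train: int = 300
    n_valid: int = 150
    factor_loading: float = 1.0
    noise_sd: float = 0.5
    n_predictive_modules: int = 6
    subtype_shift: float = 2.5
    subtype2_prob: float = 0.5
    treatment_prob: float = 0.5
    baseline_hazard: float = 0.12
    beta_treatment: float = math.log(0.5)
    beta_interaction: float = math.log(4.0)
    censoring_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_in", "p_out", "treatment_prob", "subtype2_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_in <= self.p_out:
            raise ValueError("p_in must exceed p_out")
        if self.module_size_range[0] < 2:
            raise ValueError("module sizes must be >= 2")
        if self.n_predictive_modules > self.n_modules:
            raise ValueError("n_predictive_modules exceeds n_modules")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Planted structure the pipeline is expected to recover.

    ``shift_signs`` records the direction of each predictive module's
    subtype shift: alternating +/- so that, as in real signatures, some
    modules are up-regulated in one sub-group and some in the other (a
    uniform one-directional shift would be invisible to correlation-based
    patient clustering).
    """

    module_members: dict[str, list[str]]
    predictive_modules: list[str]
    shift_signs: dict[str, int] = field(default_factory=dict)
    subtypes: dict[str, pd.Series] = field(default_factory=dict)  # cohort -> series
    factors: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_members": self.module_members,
            "predictive_modules": self.predictive_modules,
            "subtypes": {k: v.to_dict() for k, v in self.subtypes.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class CohortBundle:
    """Everything one cohort contributes to the pipeline."""

    name: str
    expression: ExpressionMatrix
    detection: DetectionMatrix
    clinical: ClinicalTable


def _gene_names(config: SyntheticConfig) -> tuple[dict[str, list[str]], list[str]]:
    lo, hi = config.module_size_range
    rng = np.random.RandomState(config.seed)
    members: dict[str, list[str]] = {}
    counter = 0
    for m in range(1, config.n_modules + 1):
        size = int(rng.randint(lo, hi + 1))
        members[f"M{m:03d}"] = [f"G{counter + i:05d}" for i in range(size)]
        counter += size
    background = [f"B{i:05d}" for i in range(config.n_background_nodes)]
    return members, background


def generate_network(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[PPINetwork, SyntheticTruth]:
    """Planted-partition network: dense modules in a sparse background.

    Within-module node pairs are connected with probability ``p_in``; all
    other pairs (including background nodes) with ``p_out``.
    """
    seed = config.seed if seed is None else seed
    members, background = _gene_names(config)
    nodes = [g for mem in members.values() for g in mem] + background
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    rng = np.random.RandomState(seed)

    block = np.zeros(n, dtype=int)  # 0 = background, 1.. = module id
    for mid, (name, mem) in enumerate(members.items(), start=1):
        for g in mem:
            block[index[g]] = mid
    same = (block[:, None] == block[None, :]) & (block[:, None] > 0)
    prob = np.where(same, config.p_in, config.p_out)
    upper = np.triu(rng.random_sample((n, n)) < prob, k=1)
    ii, jj = np.nonzero(upper)
    if ii.size == 0:
        raise ValueError("configuration produced an empty network")
    net = PPINetwork.from_edges([(nodes[i], nodes[j]) for i, j in zip(ii, jj)])
    predictive = sorted(members)[: config.n_predictive_modules]
    truth = SyntheticTruth(
        module_members={k: list(v) for k, v in members.items()},
        predictive_modules=predictive,
        shift_signs={m: (1 if i % 2 == 0 else -1) for i, m in enumerate(predictive)},
    )
    return net, truth


def _draw_cohort_latents(
    truth: SyntheticTruth, config: SyntheticConfig, rng: np.random.RandomState, n: int
) -> tuple[pd.Series, pd.DataFrame]:
    subtype = pd.Series(
        np.where(rng.random_sample(n) < config.subtype2_prob, 2, 1)
    )
    module_names = sorted(truth.module_members)
    factors = rng.standard_normal((len(module_names), n))
    sub2 = np.flatnonzero(subtype.to_numpy() == 2)
    for m in truth.predictive_modules:
        sign = truth.shift_signs.get(m, 1)
        factors[module_names.index(m), sub2] += sign * config.subtype_shift
    return subtype, pd.DataFrame(factors, index=module_names)


def generate_expression(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    seed: int,
    n_samples: int,
    sample_prefix: str = "S",
) -> tuple[ExpressionMatrix, DetectionMatrix, pd.Series, pd.DataFrame]:
    """Factor-model expression for one cohort.

    Gene i of module m in sample j: x_ij = loading * f_mj + noise, with the
    module factor f_mj standard normal, shifted by ``subtype_shift`` for
    predictive modules in subtype-2 patients; background genes are pure
    noise.  Detection flags are all-present.  Returns the matrix, flags,
    the per-sample subtype, and the latent factors.
    """
    rng = np.random.RandomState(seed)
    subtype, factors = _draw_cohort_latents(truth, config, rng, n_samples)
    samples = [f"{sample_prefix}{i:04d}" for i in range(n_samples)]
    subtype.index = pd.Index(samples)
    factors.columns = pd.Index(samples)

    module_names = sorted(truth.module_members)
    gene_rows = []
    gene_names: list[str] = []
    for m in module_names:
        for g in truth.module_members[m]:
            gene_rows.append(factors.loc[m].to_numpy() * config.factor_loading)
            gene_names.append(g)
    n_bg = config.n_background_nodes
    signal = np.vstack(gene_rows) if gene_rows else np.empty((0, n_samples))
    noise = rng.standard_normal((signal.shape[0] + n_bg, n_samples)) * config.noise_sd
    values = np.vstack([signal, np.zeros((n_bg, n_samples))]) + noise
    gene_names += [f"B{i:05d}" for i in range(n_bg)]
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=gene_names, columns=samples)
    )
    det = DetectionMatrix(
        pd.DataFrame(
            np.ones_like(values, dtype=int), index=gene_names, columns=samples
        )
    )
    return expr, det, subtype, factors


def _calibrate_uniform_censoring(
    times: np.ndarray, target: float
) -> float:
    """Upper bound c of U(0, c) censoring hitting the target censored fraction.

    With C ~ U(0, c), P(censored | T = t) = min(t / c, 1); the expected
    censored fraction is monotone decreasing in c, so c is found by
    bisection on the drawn event times.
    """
    if target <= 0:
        return math.inf

    def frac(c: float) -> float:
        return float(np.mean(np.minimum(times / c, 1.0)))

    lo, hi = 1e-9, float(times.max()) * 2 + 1e-9
    while frac(hi) > target:
        hi *= 2
    for _ in range(200):
        mid = (lo + hi) / 2
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_clinical(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    seed: int,
    subtype: pd.Series,
) -> ClinicalTable:
    """Survival table under a proportional-hazards treatment x subtype model.

    Treatment is Bernoulli(``treatment_prob``) independent of subtype;
    event times are exponential with hazard
    ``h0 * exp(b_trt * trt + b_int * trt * [subtype == 2])``; censoring is
    independent uniform, calibrated so the expected censored fraction
    matches ``censoring_rate``.  RFS and OS times are independent draws
    from the same hazard.
    """
    rng = np.random.RandomState(seed)
    n = len(subtype)
    trt = (rng.random_sample(n) < config.treatment_prob).astype(int)
    lin = config.beta_treatment * trt + config.beta_interaction * trt * (
        subtype.to_numpy() == 2
    )
    hazard = config.baseline_hazard * np.exp(lin)

    cols: dict[str, np.ndarray] = {"treatment": trt}
    for endpoint in ("rfs", "os"):
        t_event = rng.exponential(1.0 / hazard)
        c = _calibrate_uniform_censoring(t_event, config.censoring_rate)
        t_cens = (
            rng.uniform(0.0, c, size=n) if np.isfinite(c) else np.full(n, np.inf)
        )
        observed = np.minimum(t_event, t_cens)
        cols[f"{endpoint}_time"] = observed
        cols[f"{endpoint}_event"] = (t_event <= t_cens).astype(int)
    df = pd.DataFrame(cols, index=subtype.index)
    return ClinicalTable(df[
        ["rfs_time", "rfs_event", "os_time", "os_event", "treatment"]
    ])


def generate_cohorts(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[PPINetwork, CohortBundle, CohortBundle, SyntheticTruth]:
    """Two independent cohorts (training, validation) from one generative truth."""
    seed = config.seed if seed is None else seed
    network, truth = generate_network(config, seed=seed)
    bundles = []
    for i, (name, n, prefix) in enumerate(
        (("training", config.n_train, "T"), ("validation", config.n_valid, "V"))
    ):
        expr, det, subtype, factors = generate_expression(
            truth, config, seed=seed + 1 + i, n_samples=n, sample_prefix=prefix
        )
        clinical = generate_clinical(
            truth, config, seed=seed + 101 + i, subtype=subtype
        )
        truth.subtypes[name] = subtype
        truth.factors[name] = factors
        bundles.append(
            CohortBundle(name=name, expression=expr, detection=det, clinical=clinical)
        )
    return network, bundles[0], bundles[1], truth


def generate_screen_scenario(
    n_modules: int = 100,
    n_samples: int = 200,
    beta_interaction: float = 0.0,
    beta_treatment: float = 0.0,
    baseline_hazard: float = 0.12,
    censoring_rate: float = 0.2,
    treatment_prob: float = 0.5,
    seed: int = 0,
    planted_module: str = "M001",
):
    """Module-score cohort for screen calibration/power studies.

    Scores are i.i.d. standard normal per module; the hazard is
    ``h0 * exp(b_trt * trt + b_int * trt * score_planted)`` so that
    ``beta_interaction = 0`` gives a global null for the interaction
    screen and a positive value plants the interaction on one module.
    Returns (profile-like score frame, ClinicalTable, planted module id).
    """
    from .gsva import GsvaProfile

    rng = np.random.RandomState(seed)
    names = [f"M{i + 1:03d}" for i in range(n_modules)]
    samples = [f"P{i:04d}" for i in range(n_samples)]
    raw = rng.standard_normal((n_modules, n_samples))
    scores = pd.DataFrame(np.tanh(raw), index=names, columns=samples)

    trt = (rng.random_sample(n_samples) < treatment_prob).astype(int)
    planted = raw[names.index(planted_module)]
    hazard = baseline_hazard * np.exp(
        beta_treatment * trt + beta_interaction * trt * np.tanh(planted)
    )
    t_event = rng.exponential(1.0 / hazard)
    c = _calibrate_uniform_censoring(t_event, censoring_rate)
    t_cens = (
        rng.uniform(0.0, c, size=n_samples) if np.isfinite(c) else np.full(n_samples, np.inf)
    )
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "rfs_time": np.minimum(t_event, t_cens),
                "rfs_event": (t_event <= t_cens).astype(int),
                "treatment": trt,
            },
            index=samples,
        )
    )
    return GsvaProfile(scores), clinical, planted_module


def match_modules(
    modules, truth: SyntheticTruth, min_jaccard: float = 0.3
) -> dict[str, str]:
    """Map discovered modules onto planted ones by best Jaccard overlap.

    Discovered modules whose best overlap falls below ``min_jaccard`` stay
    unmatched (absent from the result).
    """
    planted = {k: set(v) for k, v in truth.module_members.items()}
    out: dict[str, str] = {}
    for name, members in modules.items():
        mem = set(members)
        best, best_j = None, 0.0
        for pname, pmem in planted.items():
            j = len(mem & pmem) / len(mem | pmem)
            if j > best_j:
                best, best_j = pname, j
        if best is not None and best_j >= min_jaccard:
            out[name] = best
    return out


def panel_jaccard(panel_names, modules, truth: SyntheticTruth) -> float:
    """Jaccard overlap between a selected panel and the planted predictive set.

    The panel's discovered modules are first matched to planted modules by
    :func:`match_modules`; the Jaccard index is then computed between the
    matched planted ids and the true predictive ids.
    """
    matching = match_modules(modules, truth)
    matched = {matching[n] for n in panel_names if n in matching}
    predictive = set(truth.predictive_modules)
    union = matched | predictive
    return len(matched & predictive) / len(union) if union else 1.0


def write_scenario(
    out_dir: str | Path,
    network: PPINetwork,
    train: CohortBundle,
    valid: CohortBundle,
    truth: SyntheticTruth,
    config: SyntheticConfig,
) -> dict[str, str]:
    """Serialize a generated scenario in the pipeline's input formats.

    Writes the edge list, per-cohort expression/detection/clinical TSVs,
    the truth JSON, and a manifest tying the files together; returns the
    manifest mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"network": "network_edges.tsv", "truth": "truth.json"}
    write_edgelist(network, out / paths["network"])
    truth.to_json(out / paths["truth"])
    for bundle in (train, valid):
        for kind in ("expression", "detection", "clinical"):
            rel = f"{bundle.name}_{kind}.tsv"
            getattr(bundle, kind).to_tsv(out / rel)
            paths[f"{bundle.name}_{kind}"] = rel
    manifest = {
        "config": dataclasses.asdict(config),
        "files": paths,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return paths
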
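"""Synthetic two-group connectome cohorts with planted rich-club structure.

The generator emulates the statistical structure a rich-club analysis of a
patient/control DTI cohort assumes:

* A cohort-level anatomical *scaffold* of edges is drawn once per cohort,
  with block-dependent density (hub-hub densest, hub-nonhub intermediate,
  nonhub-nonhub solved so the expected overall density matches ``density``).
  Each subject realizes scaffold edges with high reliability and non-scaffold
  edges at a small spurious rate — mimicking the cross-subject consistency of
  tractography that makes group-consensus backbones meaningful.
* Streamline counts (FN) on present edges are overdispersed negative-binomial
  counts whose mean is enriched on hub-hub edges by ``fn_hub_gain`` (feeder
  edges get the geometric midpoint). In the patient group the FN mean of every
  hub-involved edge is multiplied by ``group_deficit``, planting the
  rich-club/feeder strength reduction the analysis should detect.
* FA values on present edges are Beta-distributed, rescaled to (0.2, 0.9)
  (tracking masks exclude FA < 0.2); node volumes are lognormal.
* Clinical scores follow group-specific truncated-normal marginals and are
  coupled to a subject's named connection-class strength through a Gaussian
  copula, so the cohort-level Spearman correlation approaches the configured
  coupling. Age, sex and education are drawn independently of group by
  default (matched-cohort design); an optional group age shift exists for
  exercising covariate removal.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .atlas import NodeAtlas, region_labels
from .io import write_matrix
from .netbuild import RawConnectome

GROUPS = ("patient", "control")
SCALES = ("PSQI", "ISI", "SAS", "SDS")

# Group-specific clinical score marginals (mean, sd), truncated at 0.
SCORE_MARGINALS = {
    "patient": {"PSQI": (16.32, 3.76), "ISI": (20.72, 3.75),
                "SAS": (47.66, 8.59), "SDS": (52.40, 8.75)},
    "control": {"PSQI": (2.55, 2.47), "ISI": (2.63, 2.65),
                "SAS": (5.91, 10.87), "SDS": (6.97, 11.97)},
}
# Disease duration (months), lognormal, patients only.
DURATION_LOG_MEAN, DURATION_LOG_SD = math.log(24.0), 0.6

_CLASS_INDEX = {"rich-club": 0, "feeder": 1, "local": 2}


@dataclass(frozen=True)
class CovariateModel:
    """Age / sex / education generation parameters."""

    age_mean: float = 40.4
    age_sd: float = 10.3
    age_min: float = 18.0
    age_max: float = 60.0
    education_mean: float = 7.8
    education_sd: float = 4.0
    male_prob: float = 0.447
    # optional confound: added to patient mean age, for testing covariate removal
    group_age_shift: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters (defaults emulate the study design)."""

    n_nodes: int = 90
    n_hubs: int = 32
    n_group1: int = 43          # patients
    n_group2: int = 42          # controls
    fn_base: float = 20.0       # mean streamline count on local edges
    fn_hub_gain: float = 4.0    # hub-hub FN enrichment (>1)
    fn_dispersion: float = 3.0  # negative-binomial size parameter
    group_deficit: float = 0.7  # patient FN multiplier on hub-involved edges
    density: float = 0.25       # expected scaffold edge density
    hub_density: float = 0.75   # scaffold probability, hub-hub block
    feeder_density: float = 0.25
    edge_reliability: float = 0.9   # subject realizes a scaffold edge
    spurious_rate: float = 0.02     # subject realizes a non-scaffold edge
    fa_params: tuple = (4.0, 3.0)   # Beta shape parameters
    fa_range: tuple = (0.2, 0.9)
    volume_params: tuple = (7.0, 0.4)  # lognormal (mu, sigma) of node volumes
    # (scale, connection class, target Spearman rho) triples
    clinical_couplings: tuple = (
        ("ISI", "rich-club", 0.58),
        ("SDS", "rich-club", -0.31),
    )
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not 0 < self.n_hubs < self.n_nodes:
            raise ValueError("n_hubs must satisfy 0 < n_hubs < n_nodes")
        if self.n_group1 < 1 or self.n_group2 < 1:
            raise ValueError("both groups need at least one subject")
        if not 0 < self.group_deficit <= 1:
            raise ValueError("group_deficit must be in (0, 1]")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if self.fn_hub_gain <= 1:
            raise ValueError("fn_hub_gain must exceed 1")
        for scale, cls, rho in self.clinical_couplings:
            if cls not in _CLASS_INDEX:
                raise ValueError(f"unknown connection class {cls!r}")
            if not -1 < rho < 1:
                raise ValueError("couplings must lie in (-1, 1)")
        _block_probabilities(self)  # raises if the density split is infeasible

    def coupling_for(self, scale: str):
        for s, cls, rho in self.clinical_couplings:
            if s == scale:
                return cls, rho
        return None, 0.0


@dataclass
class SubjectRecord:
    """Phenotype row: group membership, covariates and clinical scores."""

    subject_id: str
    group: str
    age: float
    sex: str
    education: float
    duration: float
    PSQI: float
    ISI: float
    SAS: float
    SDS: float

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id, "group": self.group, "age": self.age,
            "sex": self.sex, "education": self.education, "duration": self.duration,
            "PSQI": self.PSQI, "ISI": self.ISI, "SAS": self.SAS, "SDS": self.SDS,
        }


# ---------------------------------------------------------------------------
# Structural helpers
# ---------------------------------------------------------------------------

def planted_hubs(config: SimulationConfig) -> np.ndarray:
    """The deterministic planted hub node set (evenly spread over the atlas)."""
    idx = np.round(np.linspace(0, config.n_nodes - 1, config.n_hubs)).astype(int)
    return np.unique(idx)


def _edge_arrays(n_nodes: int, hubs: np.ndarray):
    iu, ju = np.triu_indices(n_nodes, k=1)
    is_hub = np.zeros(n_nodes, dtype=bool)
    is_hub[hubs] = True
    block = is_hub[iu].astype(int) + is_hub[ju].astype(int)  # 2 hub-hub, 1 feeder, 0 local
    return iu, ju, block


def _block_probabilities(config: SimulationConfig) -> np.ndarray:
    """Scaffold probability per block [local, feeder, hub-hub]."""
    hubs = planted_hubs(config)
    _, _, block = _edge_arrays(config.n_nodes, hubs)
    e_total = len(block)
    e_hub = int(np.sum(block == 2))
    e_feeder = int(np.sum(block == 1))
    e_local = e_total - e_hub - e_feeder
    p_local = (
        config.density * e_total
        - config.hub_density * e_hub
        - config.feeder_density * e_feeder
    ) / max(e_local, 1)
    if not 0 < p_local < 1:
        raise ValueError(
            "infeasible density split: local-block scaffold probability "
            f"{p_local:.3f} outside (0, 1); adjust density/hub_density/feeder_density"
        )
    return np.array([p_local, config.feeder_density, config.hub_density])


_scaffold_cache: dict = {}


def _structural_key(config: SimulationConfig) -> tuple:
    return (
        config.n_nodes, config.n_hubs, config.fn_base, config.fn_hub_gain,
        config.fn_dispersion, config.density, config.hub_density,
        config.feeder_density, config.edge_reliability, config.spurious_rate,
        config.fa_params, config.fa_range, config.seed,
    )


def cohort_scaffold(config: SimulationConfig) -> np.ndarray:
    """Boolean scaffold over upper-triangle edges, fixed for a whole cohort."""
    key = _structural_key(config)
    if key not in _scaffold_cache:
        hubs = planted_hubs(config)
        _, _, block = _edge_arrays(config.n_nodes, hubs)
        probs = _block_probabilities(config)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 101]))
        if len(_scaffold_cache) > 64:
            _scaffold_cache.clear()
        _scaffold_cache[key] = rng.random(len(block)) < probs[block]
    return _scaffold_cache[key]


def _draw_connectome_edges(
    config: SimulationConfig, group: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(fn, fa) values over upper-triangle edges for one subject."""
    hubs = planted_hubs(config)
    _, _, block = _edge_arrays(config.n_nodes, hubs)
    scaffold = cohort_scaffold(config)
    p_present = np.where(scaffold, config.edge_reliability, config.spurious_rate)
    present = rng.random(len(block)) < p_present
    mean_fn = config.fn_base * config.fn_hub_gain ** (block / 2.0)
    if group == "patient":
        mean_fn = np.where(block > 0, mean_fn * config.group_deficit, mean_fn)
    nb_mean = np.maximum(mean_fn - 1.0, 0.0)
    r = config.fn_dispersion
    p_nb = r / (r + nb_mean)
    fn = np.where(present, 1 + rng.negative_binomial(r, p_nb), 0)
    lo, hi = config.fa_range
    a, b = config.fa_params
    fa = np.where(fn > 0, lo + (hi - lo) * rng.beta(a, b, len(block)), 0.0)
    return fn.astype(np.int64), fa


def _class_strengths_from_edges(
    config: SimulationConfig, atlas: NodeAtlas, fn: np.ndarray, fa: np.ndarray
) -> np.ndarray:
    """(rich, feeder, local) strengths w.r.t. planted hubs, from triu arrays."""
    hubs = planted_hubs(config)
    iu, ju, block = _edge_arrays(config.n_nodes, hubs)
    vol = (atlas.volumes[iu] + atlas.volumes[ju]) / 2.0
    w = fn * fa / vol
    return np.array([w[block == 2].sum(), w[block == 1].sum(), w[block == 0].sum()])


_moment_cache: dict = {}


def _strength_moments(config: SimulationConfig, atlas: NodeAtlas, group: str) -> np.ndarray:
    """Mean/sd of the three class strengths, estimated once per config+group.

    Used to map a subject's class strength to an approximate standard-normal
    score for the clinical-score copula. Cached; the calibration sample uses
    its own fixed child seed so cohorts remain reproducible.
    """
    deficit = config.group_deficit if group == "patient" else 1.0
    key = _structural_key(config) + (deficit, atlas.volumes.tobytes())
    if key not in _moment_cache:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 202]))
        n_cal = 200
        hubs = planted_hubs(config)
        iu, ju, block = _edge_arrays(config.n_nodes, hubs)
        scaffold = cohort_scaffold(config)
        e = len(block)
        p_present = np.where(scaffold, config.edge_reliability, config.spurious_rate)
        mean_fn = config.fn_base * config.fn_hub_gain ** (block / 2.0)
        if group == "patient":
            mean_fn = np.where(block > 0, mean_fn * config.group_deficit, mean_fn)
        r = config.fn_dispersion
        p_nb = r / (r + np.maximum(mean_fn - 1.0, 0.0))
        present = rng.random((n_cal, e)) < p_present
        fn = np.where(present, 1 + rng.negative_binomial(r, np.broadcast_to(p_nb, (n_cal, e))), 0)
        lo, hi = config.fa_range
        a, b = config.fa_params
        fa = np.where(fn > 0, lo + (hi - lo) * rng.beta(a, b, (n_cal, e)), 0.0)
        vol = (atlas.volumes[iu] + atlas.volumes[ju]) / 2.0
        w = fn * fa / vol
        draws = np.stack(
            [w[:, block == 2].sum(axis=1), w[:, block == 1].sum(axis=1), w[:, block == 0].sum(axis=1)],
            axis=1,
        )
        if len(_moment_cache) > 64:
            _moment_cache.clear()
        _moment_cache[key] = np.stack([draws.mean(axis=0), draws.std(axis=0)])
    return _moment_cache[key]


# ---------------------------------------------------------------------------
# Marginal transforms
# ---------------------------------------------------------------------------

def _tnorm_ppf(u: float, mean: float, sd: float, lo: float = 0.0, hi: float = np.inf) -> float:
    """Quantile of a normal(mean, sd) truncated to [lo, hi]."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd) if np.isfinite(hi) else 1.0
    return mean + sd * ndtri(a + u * (b - a))


def _score_value(scale: str, group: str, u: float) -> float:
    mean, sd = SCORE_MARGINALS[group][scale]
    return _tnorm_ppf(u, mean, sd, lo=0.0)


def _duration_value(group: str, u: float) -> float:
    if group != "patient":
        return 0.0
    return math.exp(DURATION_LOG_MEAN + DURATION_LOG_SD * ndtri(u))


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def generate_atlas(
    n_nodes: int,
    seed,
    volume_params: tuple = (7.0, 0.4),
    name: str | None = None,
) -> NodeAtlas:
    """Synthetic atlas: alternating hemispheres, seeded centroids and volumes."""
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    rng = np.random.default_rng(seed)
    labels = region_labels(n_nodes)
    hemis = ["L" if i % 2 == 0 else "R" for i in range(n_nodes)]
    cent = np.empty((n_nodes, 3))
    cent[:, 0] = rng.uniform(5, 70, n_nodes) * np.where([h == "L" for h in hemis], -1, 1)
    cent[:, 1] = rng.uniform(-100, 70, n_nodes)
    cent[:, 2] = rng.uniform(-45, 75, n_nodes)
    mu, sig = volume_params
    volumes = np.exp(rng.normal(mu, sig, n_nodes))
    return NodeAtlas(
        labels=np.array(labels, dtype=object),
        hemispheres=np.array(hemis, dtype=object),
        centroids=cent,
        volumes=volumes,
        name=name or f"synthetic{n_nodes}",
    )


def generate_subject(
    config: SimulationConfig, atlas: NodeAtlas, group: str, seed
) -> tuple[SubjectRecord, RawConnectome]:
    """One subject: raw connectome plus phenotype record.

    Clinical scores coupled to a connection class are drawn through a
    Gaussian copula between the subject's realized class strength (normal
    score via calibrated moments) and the score's truncated-normal marginal;
    the copula parameter is ``2 sin(pi rho / 6)`` so the target ``rho`` is
    the Spearman correlation.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    if atlas.n_nodes != config.n_nodes:
        raise ValueError("atlas size does not match config.n_nodes")
    rng = np.random.default_rng(seed)
    fn_e, fa_e = _draw_connectome_edges(config, group, rng)
    iu, ju, _ = _edge_arrays(config.n_nodes, planted_hubs(config))
    n = config.n_nodes
    fn = np.zeros((n, n), dtype=np.int64)
    fa = np.zeros((n, n))
    fn[iu, ju] = fn_e
    fa[iu, ju] = fa_e
    fn = fn + fn.T
    fa = fa + fa.T
    raw = RawConnectome(fn=fn, fa=fa, volumes=atlas.volumes.copy())

    cm = config.covariate_model
    age_mean = cm.age_mean + (cm.group_age_shift if group == "patient" else 0.0)
    age = _tnorm_ppf(rng.random(), age_mean, cm.age_sd, lo=cm.age_min, hi=cm.age_max)
    education = _tnorm_ppf(rng.random(), cm.education_mean, cm.education_sd, lo=0.0)
    sex = "male" if rng.random() < cm.male_prob else "female"

    strengths = _class_strengths_from_edges(config, atlas, fn_e, fa_e)
    scores = {}
    for scale in SCALES + ("duration",):
        cls, rho = config.coupling_for(scale)
        if cls is not None and rho != 0.0:
            mom = _strength_moments(config, atlas, group)
            ci = _CLASS_INDEX[cls]
            z_s = (strengths[ci] - mom[0, ci]) / max(mom[1, ci], 1e-12)
            r = 2.0 * math.sin(math.pi * rho / 6.0)
            z = r * z_s + math.sqrt(1.0 - r * r) * rng.standard_normal()
            u = float(ndtr(z))
        else:
            u = float(rng.random())
        u = min(max(u, 1e-12), 1 - 1e-12)
        scores[scale] = _duration_value(group, u) if scale == "duration" else _score_value(scale, group, u)

    record = SubjectRecord(
        subject_id="", group=group, age=float(age), sex=sex,
        education=float(education), duration=float(scores["duration"]),
        PSQI=float(scores["PSQI"]), ISI=float(scores["ISI"]),
        SAS=float(scores["SAS"]), SDS=float(scores["SDS"]),
    )
    return record, raw


def generate_cohort(
    config: SimulationConfig,
) -> tuple[NodeAtlas, list[tuple[SubjectRecord, RawConnectome]]]:
    """Full two-group cohort, fully reproducible from ``config.seed``."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + config.n_group1 + config.n_group2)
    atlas = generate_atlas(config.n_nodes, children[0], config.volume_params)
    subjects = []
    k = 1
    for group, count, tag in (("patient", config.n_group1, "P"), ("control", config.n_group2, "C")):
        for i in range(count):
            rec, raw = generate_subject(config, atlas, group, children[k])
            rec.subject_id = f"sub-{tag}{i + 1:03d}"
            subjects.append((rec, raw))
            k += 1
    return atlas, subjects


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def phenotype_frame(subjects) -> pd.DataFrame:
    return pd.DataFrame([rec.to_dict() for rec, _ in subjects])


def write_cohort(out_dir, atlas: NodeAtlas, subjects) -> None:
    """Write atlas CSV, phenotype CSV and per-subject FN/FA matrix TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas.to_csv(out / "atlas.csv")
    phenotype_frame(subjects).to_csv(out / "phenotype.csv", index=False)
    for rec, raw in subjects:
        write_matrix(out / f"{rec.subject_id}_fn.tsv", raw.fn, atlas.name)
        write_matrix(out / f"{rec.subject_id}_fa.tsv", raw.fa, atlas.name)


def read_cohort(in_dir) -> tuple[NodeAtlas, list[tuple[SubjectRecord, RawConnectome]]]:
    """Read a cohort previously written by :func:`write_cohort`."""
    from .io import read_matrix

    d = Path(in_dir)
    atlas = NodeAtlas.from_csv(d / "atlas.csv")
    pheno = pd.read_csv(d / "phenotype.csv")
    subjects = []
    for _, row in pheno.iterrows():
        fn, _ = read_matrix(d / f"{row.subject_id}_fn.tsv")
        fa, _ = read_matrix(d / f"{row.subject_id}_fa.tsv")
        raw = RawConnectome(fn=fn.astype(np.int64), fa=fa, volumes=atlas.volumes.copy())
        rec = SubjectRecord(
            subject_id=row.subject_id, group=row.group, age=row.age, sex=row.sex,
            education=row.education, duration=row.duration, PSQI=row.PSQI,
            ISI=row.ISI, SAS=row.SAS, SDS=row.SDS,
        )
        subjects.append((rec, raw))
    return atlas, subjects
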
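"""End-to-end orchestration: simulate -> build -> consensus -> metrics ->
rich club -> group tests / correlations -> report.

A single :class:`RunConfig` (optionally loaded from YAML) drives every stage.
All randomness flows from explicit seeds: the cohort from ``config.sim.seed``
and each stochastic analysis stage from counter-derived children of
``config.seed``, so stages can be re-run in isolation and the full report is
byte-reproducible.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .netbuild import build_network, group_consensus
from .metrics import small_world_indices, sparsity_auc, sparsity_grid
from .richclub import (
    export_brainnet,
    identify_rich_nodes,
    normalized_rich_club,
    subject_class_strengths,
)
from .stats import (
    benjamini_hochberg,
    chi_square_2x2,
    holm_bonferroni,
    mann_whitney_u,
    permutation_group_test,
    spearman_partial,
)
from .synthgen import SCALES, SimulationConfig, generate_cohort, phenotype_frame

GLOBAL_METRICS = ("cp", "lp", "eg", "eloc")
CLASS_COLUMNS = ("rich_club", "feeder", "local")


@dataclass
class RunConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    fn_thresholds: tuple = (1, 2, 3, 5, 10)
    prevalence_levels: tuple = (0.5, 0.75, 0.9)
    main_fn_threshold: int = 1
    main_prevalence: float = 0.75
    sparsity: tuple = (0.10, 0.40, 0.01)
    n_null: int = 1000
    n_perm: int = 10000
    grid_n_perm: int | None = None   # permutations for the reproducibility grid
    top_n_rich: int = 32
    correction: str = "holm"         # or "fdr_bh"
    shared_rich_set: bool = False    # use the two groups' intersection instead
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        if self.main_fn_threshold not in self.fn_thresholds:
            raise ValueError("main_fn_threshold must be one of fn_thresholds")
        if any(t < 1 for t in self.fn_thresholds):
            raise ValueError("FN thresholds must be >= 1")
        if any(not 0 < p <= 1 for p in self.prevalence_levels):
            raise ValueError("prevalence levels must be in (0, 1]")
        if not 0 < self.top_n_rich < self.sim.n_nodes:
            raise ValueError("top_n_rich must be in 1..n_nodes-1")
        if self.correction not in ("holm", "fdr_bh"):
            raise ValueError("correction must be 'holm' or 'fdr_bh'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**data.pop("sim", {}))
        return cls(sim=sim, **{k: tuple(v) if isinstance(v, list) else v for k, v in data.items()})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class AnalysisReport:
    demographics: dict
    global_comparison: list
    small_world: dict
    rich_club: dict
    class_comparison: dict
    correlations: list
    reproducibility: list
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _round_floats(obj, ndigits: int = 12):
    """Fixed-precision serialization so identical runs are byte-identical."""
    if isinstance(obj, float):
        return float(f"{obj:.{ndigits}g}") if np.isfinite(obj) else None
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    if isinstance(obj, dict):
        return {str(k): _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _child_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, stage]).generate_state(1)[0] % (2**31))


def _adjust(p_values, method: str):
    adj, rej = (holm_bonferroni(p_values) if method == "holm" else benjamini_hochberg(p_values))
    return adj, rej


def demographics_table(subjects) -> pd.DataFrame:
    """Group means +/- SD and p-values, laid out like a cohort table.

    Rows: age, sex, education, PSQI, ISI, SAS, SDS. Quantitative rows use the
    Mann-Whitney U test; the sex row uses the Pearson chi-square test.
    """
    pheno = phenotype_frame(subjects) if not isinstance(subjects, pd.DataFrame) else subjects
    groups = [g for g in ("patient", "control") if g in set(pheno.group)]
    if len(groups) != 2:
        raise ValueError("demographics table needs both groups")
    pat = pheno[pheno.group == "patient"]
    con = pheno[pheno.group == "control"]
    rows = []
    quant = [("age", "age"), ("education", "education")] + [(s, s) for s in SCALES]
    order = ["age", "sex", "education", "PSQI", "ISI", "SAS", "SDS"]
    cells = {}
    for name, col in quant:
        _, p = mann_whitney_u(pat[col], con[col])
        cells[name] = {
            "patient": f"{pat[col].mean():.2f} ± {pat[col].std():.2f}",
            "control": f"{con[col].mean():.2f} ± {con[col].std():.2f}",
            "p": p,
            "test": "mann-whitney",
        }
    table = [
        [(pat.sex == "male").sum(), (pat.sex == "female").sum()],
        [(con.sex == "male").sum(), (con.sex == "female").sum()],
    ]
    _, p_sex = chi_square_2x2(np.array(table).T)
    cells["sex"] = {
        "patient": f"{table[0][0]}/{table[0][1]}",
        "control": f"{table[1][0]}/{table[1][1]}",
        "p": p_sex,
        "test": "chi-square",
    }
    for name in order:
        row = cells[name]
        rows.append({"characteristic": name, **row})
    return pd.DataFrame(rows).set_index("characteristic")


def _covariate_frame(pheno: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": pheno.age.to_numpy(float),
            "sex": (pheno.sex == "male").astype(float).to_numpy(),
            "education": pheno.education.to_numpy(float),
        },
        index=pheno.index,
    )


def _rich_sets(nets_by_group: dict, prevalence: float, top_n: int, shared: bool) -> dict:
    sets = {
        g: identify_rich_nodes(group_consensus(nets, prevalence).to_network(), top_n=top_n)
        for g, nets in nets_by_group.items()
    }
    if shared:
        inter = sets["patient"] & sets["control"]
        return {g: inter for g in sets}
    return sets


def _class_comparison(
    nets_by_group, pheno, prevalence, top_n, shared, n_perm, seed, correction
):
    """Permutation tests on rich/feeder/local strengths (covariates removed)."""
    rich_sets = _rich_sets(nets_by_group, prevalence, top_n, shared)
    strengths = {
        g: subject_class_strengths(nets, rich_sets[g]) for g, nets in nets_by_group.items()
    }
    cov = pd.concat(
        [
            _covariate_frame(pheno[pheno.group == "patient"]),
            _covariate_frame(pheno[pheno.group == "control"]),
        ],
        ignore_index=True,
    )
    results = {}
    p_raws = []
    for i, cls in enumerate(CLASS_COLUMNS):
        res = permutation_group_test(
            strengths["patient"][cls],
            strengths["control"][cls],
            covariates=cov,
            n_perm=n_perm,
            seed=_child_seed(seed, 300 + i),
        )
        results[cls] = res
        p_raws.append(res.p_raw)
    adj, _ = _adjust(p_raws, correction)
    out = {}
    for i, cls in enumerate(CLASS_COLUMNS):
        r = results[cls]
        r.p_adjusted = float(adj[i])
        r.method = correction
        out[cls] = {
            "observed_patient_minus_control": r.observed,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "n_perm": r.n_perm,
            "method": correction,
        }
    mean_ratios = {
        g: {
            "rich/feeder": float(np.mean(s["rich_club"] / s["feeder"])),
            "rich/local": float(np.mean(s["rich_club"] / s["local"])),
        }
        for g, s in strengths.items()
    }
    return out, rich_sets, strengths, mean_ratios


def run_pipeline(config: RunConfig, out_dir=None) -> AnalysisReport:
    """Execute every stage and return (and optionally write) the full report."""
    config.validate()
    grid_n_perm = config.grid_n_perm or config.n_perm

    # --- cohort -----------------------------------------------------------
    atlas, subjects = generate_cohort(config.sim)
    pheno = phenotype_frame(subjects)
    demo = demographics_table(subjects)

    # --- per-subject networks at every FN threshold ------------------------
    nets_by_thr = {
        thr: [build_network(raw, thr, atlas=atlas) for _, raw in subjects]
        for thr in config.fn_thresholds
    }
    groups = pheno.group.to_numpy()

    def split(nets):
        return {
            "patient": [n for n, g in zip(nets, groups) if g == "patient"],
            "control": [n for n, g in zip(nets, groups) if g == "control"],
        }

    main_nets = nets_by_thr[config.main_fn_threshold]
    by_group = split(main_nets)

    # --- global metric AUCs + group comparison -----------------------------
    grid = sparsity_grid(*config.sparsity)
    aucs = {m: [] for m in GLOBAL_METRICS}
    per_threshold = {m: [] for m in GLOBAL_METRICS}
    for net in main_nets:
        for m in GLOBAL_METRICS:
            curve = sparsity_auc(net, m, grid)
            aucs[m].append(curve.auc)
            per_threshold[m].append(curve.values)
    cov = pd.concat(
        [
            _covariate_frame(pheno[pheno.group == "patient"]),
            _covariate_frame(pheno[pheno.group == "control"]),
        ],
        ignore_index=True,
    )
    is_pat = groups == "patient"
    global_rows = []
    p_raws = []
    for i, m in enumerate(GLOBAL_METRICS):
        a = np.asarray(aucs[m])
        res = permutation_group_test(
            a[is_pat], a[~is_pat], covariates=cov,
            n_perm=config.n_perm, seed=_child_seed(config.seed, 100 + i),
        )
        vals = np.asarray(per_threshold[m])
        global_rows.append(
            {
                "metric": m,
                "auc_patient_mean": float(a[is_pat].mean()),
                "auc_control_mean": float(a[~is_pat].mean()),
                "observed_patient_minus_control": res.observed,
                "p_raw": res.p_raw,
                "per_threshold_patient_mean": vals[is_pat].mean(axis=0),
                "per_threshold_control_mean": vals[~is_pat].mean(axis=0),
            }
        )
        p_raws.append(res.p_raw)
    adj, _ = _adjust(p_raws, config.correction)
    for row, a in zip(global_rows, adj):
        row["p_adjusted"] = float(a)

    # --- group backbones: small-world + rich-club curves -------------------
    small_world = {}
    rich_curves = {}
    for gi, g in enumerate(("patient", "control")):
        backbone = group_consensus(by_group[g], config.main_prevalence).to_network()
        sw = small_world_indices(
            backbone, n_null=config.n_null, seed=_child_seed(config.seed, 200 + gi)
        )
        small_world[g] = {
            "cp": sw.cp, "lp": sw.lp, "gamma": sw.gamma, "lambda": sw.lam,
            "sigma": sw.sigma, "n_null": config.n_null,
        }
        curve = normalized_rich_club(
            backbone, n_null=config.n_null, seed=_child_seed(config.seed, 210 + gi)
        )
        rich_curves[g] = {
            "k": curve.k_grid, "phi_w": curve.phi_w,
            "phi_null_mean": curve.phi_null_mean, "phi_null_sd": curve.phi_null_sd,
            "phi_norm": curve.phi_norm, "n_null": curve.n_null,
        }

    # --- rich/feeder/local comparison at the main configuration ------------
    class_cmp, rich_sets, strengths, ratios = _class_comparison(
        by_group, pheno, config.main_prevalence, config.top_n_rich,
        config.shared_rich_set, config.n_perm, config.seed, config.correction,
    )
    class_comparison = {
        "tests": class_cmp,
        "rich_nodes": {g: sorted(rich_sets[g]) for g in rich_sets},
        "shared_rich_nodes": sorted(rich_sets["patient"] & rich_sets["control"]),
        "mean_strength": {
            g: {c: float(strengths[g][c].mean()) for c in CLASS_COLUMNS} for g in strengths
        },
        "strength_ratios": ratios,
    }

    # --- clinical correlations (patients, covariates removed) --------------
    pat_pheno = pheno[pheno.group == "patient"].reset_index(drop=True)
    pat_str = strengths["patient"].reset_index(drop=True)
    pat_cov = _covariate_frame(pat_pheno)
    correlations = []
    for scale in SCALES + ("duration",):
        fam_p = []
        fam_rows = []
        for cls in CLASS_COLUMNS:
            r = spearman_partial(pat_pheno[scale], pat_str[cls], covariates=pat_cov)
            fam_rows.append(
                {"scale": scale, "class": cls, "rho": r.rho, "p_raw": r.p, "n": r.n}
            )
            fam_p.append(r.p if np.isfinite(r.p) else 1.0)
        adj, _ = _adjust(fam_p, config.correction)
        for row, a in zip(fam_rows, adj):
            row["p_adjusted"] = float(a)
            correlations.append(row)

    # --- reproducibility grid ----------------------------------------------
    reproducibility = []
    for ti, thr in enumerate(config.fn_thresholds):
        thr_groups = split(nets_by_thr[thr])
        for pi, prev in enumerate(config.prevalence_levels):
            cmp_out, _, _, _ = _class_comparison(
                thr_groups, pheno, prev, config.top_n_rich, config.shared_rich_set,
                grid_n_perm, _child_seed(config.seed, 1000 + 10 * ti + pi),
                config.correction,
            )
            block = {"fn_threshold": thr, "prevalence": prev, "tests": cmp_out}
            block["rich_deficit_in_patients"] = bool(
                cmp_out["rich_club"]["observed_patient_minus_control"] < 0
            )
            reproducibility.append(block)

    config_json = json.dumps(_round_floats(config.to_dict()), sort_keys=True)
    report = AnalysisReport(
        demographics=demo.reset_index().to_dict(orient="records"),
        global_comparison=global_rows,
        small_world=small_world,
        rich_club=rich_curves,
        class_comparison=class_comparison,
        correlations=correlations,
        reproducibility=reproducibility,
        provenance={
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
            "seed": config.seed,
            "richconn_version": __version__,
        },
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report_json(report))
        demo.to_csv(out / "demographics.csv")
        pd.DataFrame(correlations).to_csv(out / "correlations.csv", index=False)
        pd.DataFrame(
            [
                {"metric": r["metric"], "p_raw": r["p_raw"], "p_adjusted": r["p_adjusted"],
                 "observed": r["observed_patient_minus_control"]}
                for r in global_rows
            ]
        ).to_csv(out / "global_metrics.csv", index=False)
        for g in ("patient", "control"):
            backbone = group_consensus(by_group[g], config.main_prevalence).to_network()
            export_brainnet(
                backbone, rich_sets[g], atlas,
                out / f"{g}_backbone.node", out / f"{g}_backbone.edge",
            )
    return report


def report_json(report: AnalysisReport) -> str:
    return json.dumps(_round_floats(report.to_dict()), sort_keys=True, indent=1)
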
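"""End-to-end orchestration: synthesize, estimate, compare, map, classify.

Runs the full analysis on a synthetic cohort with one declarative config:
cohort synthesis -> per-subject Hurst maps -> normalization to controls
and ipsi/contra sorting -> region-wise group comparison with FDR ->
network spreading + epicenter mapping under spin/rewired nulls ->
case-control classification. Every stage derives its randomness from the
single config seed, so a run is fully reproducible; stages whose config
has not changed are skipped on rerun via content hashing.

Cohort directories use plain tab-delimited text: one T x N series per
subject, a subjects.tsv covariate table, connectome.tsv / dist.tsv /
parcellation.tsv, and truth.json for synthetic ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from eibm import clf, gstats, netmap
from eibm.fractal import hurst_map
from eibm.synthcohort import (
    Cohort,
    CohortSpec,
    Connectome,
    Parcellation,
    SubjectRecord,
    make_cohort,
)

__all__ = [
    "RunConfig",
    "run",
    "read_cohort",
    "write_cohort",
    "write_report",
]

logger = logging.getLogger(__name__)


# --- cohort serialization --------------------------------------------------


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Serialize a cohort as tab-delimited text plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    parc = cohort.parcellation
    pd.DataFrame(
        {
            "region_id": np.arange(parc.n_regions),
            "hemisphere": parc.hemisphere,
            "x": parc.centroids[:, 0],
            "y": parc.centroids[:, 1],
            "z": parc.centroids[:, 2],
            "community": parc.community,
        }
    ).to_csv(out / "parcellation.tsv", sep="\t", index=False)
    region_cols = [str(i) for i in range(parc.n_regions)]
    pd.DataFrame(cohort.connectome.sc, columns=region_cols).to_csv(
        out / "connectome.tsv", sep="\t", index=False, float_format="%.17g"
    )
    pd.DataFrame(cohort.connectome.dist, columns=region_cols).to_csv(
        out / "dist.tsv", sep="\t", index=False, float_format="%.17g"
    )
    rows = []
    for s in cohort.subjects:
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "focus_side": s.focus_side,
            "age": s.age,
            "sex": s.sex,
        }
        for k, v in s.cognition.items():
            row[f"cognition_{k}"] = v
        rows.append(row)
        pd.DataFrame(s.ts, columns=region_cols).to_csv(
            out / f"ts_{s.subject_id}.tsv", sep="\t", index=False, float_format="%.17g"
        )
    pd.DataFrame(rows).to_csv(out / "subjects.tsv", sep="\t", index=False)
    if cohort.truth is not None:
        truth = {}
        for k, v in cohort.truth.items():
            if isinstance(v, np.ndarray):
                truth[k] = v.tolist()
            elif dataclasses.is_dataclass(v):
                truth[k] = _jsonable(dataclasses.asdict(v))
            else:
                truth[k] = v
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed TSV {path.name}: {exc}") from exc


def read_cohort(cohort_dir: str | Path) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`.

    Unknown covariate columns are carried through with a warning; missing
    files or ragged rows raise with the offending file named.
    """
    d = Path(cohort_dir)
    parc_df = _read_tsv(d / "parcellation.tsv")
    parc = Parcellation(
        centroids=parc_df[["x", "y", "z"]].to_numpy(),
        hemisphere=parc_df["hemisphere"].to_numpy(),
        community=parc_df["community"].to_numpy(),
    )
    sc = _read_tsv(d / "connectome.tsv").to_numpy(dtype=float)
    dist = _read_tsv(d / "dist.tsv").to_numpy(dtype=float)
    subs = _read_tsv(d / "subjects.tsv")
    known = {"subject_id", "group", "focus_side", "age", "sex"}
    extra = [c for c in subs.columns if c not in known and not c.startswith("cognition_")]
    if extra:
        warnings.warn(f"unknown column(s) in subjects.tsv carried through: {extra}")
    subjects = []
    n = parc.n_regions
    for _, row in subs.iterrows():
        ts = _read_tsv(d / f"ts_{row['subject_id']}.tsv").to_numpy(dtype=float)
        if ts.shape[1] != n:
            raise ValueError(
                f"ts_{row['subject_id']}.tsv has {ts.shape[1]} columns, expected {n}"
            )
        cognition = {
            c[len("cognition_"):]: float(row[c])
            for c in subs.columns
            if c.startswith("cognition_")
        }
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                focus_side=str(row["focus_side"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                ts=ts,
                cognition=cognition,
            )
        )
    truth = None
    if (d / "truth.json").exists():
        truth = json.loads((d / "truth.json").read_text())
    return Cohort(
        parcellation=parc,
        connectome=Connectome(sc=sc, dist=dist),
        subjects=subjects,
        truth=truth,
    )


# --- run configuration -----------------------------------------------------


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    seed: int = 0
    cohort: CohortSpec = field(default_factory=lambda: CohortSpec(
        n_controls=20, n_patients=20, n_regions=68, n_timepoints=512,
        affected_regions=tuple(range(0, 10)), delta_h=0.15,
    ))
    # stage toggles
    do_netmap: bool = True
    do_classify: bool = True
    # stage parameters
    fdr_alpha: float = 0.05
    n_spin: int = 500
    n_rewired: int = 100
    clf_k_percent: float = 10.0
    clf_n_folds: int = 4
    clf_n_iterations: int = 50

    def to_json(self) -> str:
        return json.dumps(_jsonable(dataclasses.asdict(self)), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        cohort = raw.pop("cohort", None)
        cfg = cls(**raw)
        if cohort is not None:
            cohort["affected_regions"] = tuple(cohort.get("affected_regions", ()))
            if "age_range" in cohort:
                cohort["age_range"] = tuple(cohort["age_range"])
            cfg.cohort = CohortSpec(**cohort)
        return cfg

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _subject_h_maps(cohort: Cohort) -> tuple[np.ndarray, np.ndarray, dict]:
    """Hurst maps per subject, z-scored to controls and ipsi-sorted."""
    parc = cohort.parcellation
    ctrl_maps, pt_maps = [], []
    covars = {"age": [], "sex": [], "group": []}
    raw = {}
    for s in cohort.subjects:
        h = hurst_map(s.ts)
        h = gstats.flip_to_ipsi(h, s.focus_side, parc)
        raw[s.subject_id] = h
        (ctrl_maps if s.group == "control" else pt_maps).append(h)
        covars["age"].append(s.age)
        covars["sex"].append(s.sex)
        covars["group"].append(s.group)
    return np.array(ctrl_maps), np.array(pt_maps), {"covariates": covars, "raw": raw}


def run(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages in dependency order; return the report.

    Stage outputs land in ``out_dir``; a stage is skipped when its output
    exists and was produced under the same config hash. The report
    collects headline numbers (group mean H, global Cohen's d,
    significant-region count, top epicenters, classifier metrics) plus
    references to the files each number came from.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(
            ["cohort", "spin", "rewired", "classify"], ss.spawn(4)
        )
    }
    report: dict = {
        "config_hash": config.config_hash,
        "seeds": seeds,
        "stages": {},
    }
    t_all = time.time()

    # --- cohort ---
    cohort_dir = out / "cohort"
    stamp = out / "cohort.hash"
    if stamp.exists() and stamp.read_text() == config.config_hash:
        logger.info("cohort up to date; skipping synthesis")
        cohort = read_cohort(cohort_dir)
    else:
        t0 = time.time()
        cohort = make_cohort(config.cohort, seed=seeds["cohort"])
        write_cohort(cohort, cohort_dir)
        stamp.write_text(config.config_hash)
        report["stages"]["cohort"] = {"wall_time_s": round(time.time() - t0, 2)}

    # --- Hurst maps + comparison ---
    t0 = time.time()
    ctrl_maps, pt_maps, meta = _subject_h_maps(cohort)
    pt_z, ctrl_z = gstats.zscore_to_controls(pt_maps, ctrl_maps)
    age = np.array(
        [s.age for s in cohort.controls] + [s.age for s in cohort.patients]
    )
    sex = np.array(
        [s.sex for s in cohort.controls] + [s.sex for s in cohort.patients]
    )
    comp = gstats.compare_regions(ctrl_z, pt_z, age, sex, alpha=config.fdr_alpha)
    comp_df = pd.DataFrame(
        {
            "region_id": np.arange(len(comp.t)),
            "cohens_d": comp.cohens_d,
            "t": comp.t,
            "p": comp.p,
            "q": comp.q,
            "significant": comp.significant,
        }
    )
    comp_df.to_csv(out / "comparison.tsv", sep="\t", index=False)
    global_d = float(
        gstats.compare_regions(
            ctrl_z.mean(axis=1, keepdims=True),
            pt_z.mean(axis=1, keepdims=True),
            age, sex,
        ).cohens_d[0]
    )
    report["hurst"] = {
        "mean_h_controls": float(ctrl_maps.mean()),
        "mean_h_patients": float(pt_maps.mean()),
        "global_cohens_d": global_d,
        "n_significant": int(comp.significant.sum()),
        "files": ["comparison.tsv"],
        "wall_time_s": round(time.time() - t0, 2),
    }

    # --- network mapping ---
    if config.do_netmap:
        t0 = time.time()
        d_map = comp.cohens_d
        sc = cohort.connectome.sc
        coupling = netmap.node_neighbor_coupling(d_map, sc)
        spearman = lambda a, b: float(sp_stats.spearmanr(a, b).statistic)  # noqa: E731
        spin = netmap.spin_pvalue(
            spearman,
            d_map,
            netmap.neighbor_alteration(d_map, sc),
            cohort.parcellation,
            n=config.n_spin,
            seed=seeds["spin"],
        )
        rewired = netmap.rewired_pvalue(
            netmap.node_neighbor_coupling,
            d_map, sc, cohort.connectome.dist,
            n_null=config.n_rewired, seed=seeds["rewired"],
        )
        epi = netmap.epicenter_likelihood(d_map, sc)
        top_k = np.argsort(epi["rank"])[:5]
        netmap_report = {
            "neighbor_coupling": coupling,
            "p_spin": spin.p_value,
            "p_rewired": rewired.p_value,
            "top_epicenters": top_k.tolist(),
            "wall_time_s": round(time.time() - t0, 2),
        }
        (out / "netmap.json").write_text(json.dumps(_jsonable(netmap_report), indent=1))
        report["netmap"] = netmap_report

    # --- classification ---
    if config.do_classify:
        t0 = time.time()
        maps = np.vstack([ctrl_z, pt_z])
        labels = np.concatenate([np.zeros(len(ctrl_z), int), np.ones(len(pt_z), int)])
        cfg = clf.ClassifierConfig(
            k_percent=config.clf_k_percent,
            n_folds=config.clf_n_folds,
            n_iterations=config.clf_n_iterations,
        )
        rep = clf.crossval_classify(maps, labels, cfg, seed=seeds["classify"])
        report["classifier"] = {
            **rep.summary,
            "wall_time_s": round(time.time() - t0, 2),
        }

    report["total_wall_time_s"] = round(time.time() - t_all, 2)
    write_report(report, out)
    return report


def write_report(report: dict, out_dir: str | Path) -> Path:
    path = Path(out_dir) / "report.json"
    path.write_text(json.dumps(_jsonable(report), indent=1, sort_keys=True))
    return path
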
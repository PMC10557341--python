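"""Configuration-driven orchestration of the full analysis.

simulate -> GRS -> one-sample MR -> factorial MR -> sensitivity, each
stage reading and writing delimited text under one output directory so
any stage can be rerun from cached intermediates.  One master seed fans
out to per-stage seeds by stable hashing; every result table carries
the config hash and seed in a leading comment line, and a
run_metadata.json records the config echo plus the n/events/exclusion
accounting of every filter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import factorial as fmr
from . import grs as grs_mod
from . import sensitivity as sens
from . import synth
from .onesample import tsps_cox
from .synth import SimScenario

logger = logging.getLogger(__name__)


@dataclass
class TraitConfig:
    """One exposure trait and the generator settings for its instrument."""

    name: str = "trait_a"
    kind: str = "continuous"  # or "binary"
    m: int = 50
    variance_explained: float = 0.02
    true_log_hr: float = 0.0
    prevalence: float = 0.3
    weighted_grs: bool = True
    scale_doubling: bool = False


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "mr_out"
    n: int = 20_000
    covariates: Sequence[str] = field(default_factory=lambda: ["age", "sex"])
    n_boot: int = 200
    trait_a: TraitConfig = field(
        default_factory=lambda: TraitConfig(
            name="trait_a", true_log_hr=float(np.log(1.25))
        )
    )
    trait_b: TraitConfig = field(
        default_factory=lambda: TraitConfig(name="trait_b")
    )
    baseline_hazard_rate: float = 0.002
    admin_censor_time: float = 12.0
    confounding: float = 0.3
    prevalent_fraction: float = 0.01
    exclude_medication: bool = False
    medication_column: str = "sleep_medication"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        for key in ("trait_a", "trait_b"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = TraitConfig(**raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        # outdir is deployment detail, not analysis identity
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        canon = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _scenario_for(cfg: RunConfig, trait: TraitConfig, salt: str) -> SimScenario:
    return SimScenario(
        n=cfg.n,
        m=trait.m,
        variance_explained=trait.variance_explained,
        exposure_kind=(
            "continuous" if trait.kind == "continuous" else "binary-liability"
        ),
        prevalence=trait.prevalence,
        confounder_effect_on_exposure=cfg.confounding,
        confounder_effect_on_log_hazard=cfg.confounding,
        true_log_hr=trait.true_log_hr,
        baseline_hazard_rate=cfg.baseline_hazard_rate,
        admin_censor_time=cfg.admin_censor_time,
        prevalent_fraction=cfg.prevalent_fraction,
        seed=stage_seed(cfg.seed, salt),
    )


def stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    """Two-trait synthetic cohort: both exposures act on one hazard."""
    sc_a = _scenario_for(cfg, cfg.trait_a, "simulate:a")
    sc_b = _scenario_for(cfg, cfg.trait_b, "simulate:b")

    var_a = synth.simulate_variants(
        sc_a.m, sc_a.eaf_range, sc_a.beta_mean, sc_a.beta_sd,
        seed=sc_a.rng(0),
    )
    var_b = synth.simulate_variants(
        sc_b.m, sc_b.eaf_range, sc_b.beta_mean, sc_b.beta_sd,
        seed=sc_b.rng(0),
    )
    geno_a = synth.simulate_genotypes(cfg.n, var_a, seed=sc_a.rng(1))
    geno_b = synth.simulate_genotypes(cfg.n, var_b, seed=sc_b.rng(1))
    geno_b.sample_ids = geno_a.sample_ids
    x_a, u_a = synth.simulate_exposure(geno_a, var_a, sc_a)
    x_b, u_b = synth.simulate_exposure(geno_b, var_b, sc_b)

    # second trait contributes to the same hazard via an offset
    if sc_b.exposure_kind == "continuous":
        extra = sc_b.true_log_hr * (x_b - x_b.mean())
    else:
        extra = sc_b.true_log_hr * x_b
    extra = extra + sc_b.confounder_effect_on_log_hazard * u_b
    surv = synth.simulate_survival(
        x_a, u_a, sc_a, genotypes=geno_a, extra_log_hazard=extra
    )

    rng = np.random.default_rng(stage_seed(cfg.seed, "simulate:extras"))
    cohort = pd.DataFrame(
        {
            "sample_id": geno_a.sample_ids,
            cfg.trait_a.name: x_a,
            cfg.trait_b.name: x_b,
            "age": rng.normal(56.0, 8.0, size=cfg.n),
            "sex": rng.integers(0, 2, size=cfg.n).astype(float),
            cfg.medication_column: (rng.random(cfg.n) < 0.03).astype(int),
            "confounder_u_a": u_a,
            "confounder_u_b": u_b,
        }
    )
    cohort = pd.concat([cohort, surv], axis=1)

    synth.write_weights_tsv(var_a, outdir / "weights_a.tsv")
    synth.write_weights_tsv(var_b, outdir / "weights_b.tsv")
    synth.write_genotypes_tsv(geno_a, outdir / "genotypes_a.tsv")
    synth.write_genotypes_tsv(geno_b, outdir / "genotypes_b.tsv")
    _write_table(cohort, outdir / "cohort.csv", cfg)
    return {
        "n": cfg.n,
        "events": int(cohort["event"].sum()),
        "prevalent": int(cohort["prevalent"].sum()),
    }


def _load_analysis_set(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    cohort = read_table(outdir / "cohort.csv")
    n0 = len(cohort)
    cohort = cohort[cohort["prevalent"] == 0].reset_index(drop=True)
    n_prev = n0 - len(cohort)
    n_med = 0
    if cfg.exclude_medication and cfg.medication_column in cohort.columns:
        keep = cohort[cfg.medication_column] == 0
        n_med = int((~keep).sum())
        cohort = cohort[keep].reset_index(drop=True)
    logger.info(
        "analysis set: %d rows (%d prevalent excluded, %d medication "
        "users excluded)", len(cohort), n_prev, n_med,
    )
    cohort.attrs["exclusions"] = {"prevalent": n_prev, "medication": n_med}
    return cohort


def stage_grs(cfg: RunConfig, outdir: Path) -> dict:
    cohort = _load_analysis_set(cfg, outdir)
    ids = set(cohort["sample_id"].astype(str))
    rows, strength_rows = [], []
    for trait, wfile, gfile in (
        (cfg.trait_a, "weights_a.tsv", "genotypes_a.tsv"),
        (cfg.trait_b, "weights_b.tsv", "genotypes_b.tsv"),
    ):
        weights = synth.read_weights_tsv(outdir / wfile)
        geno = synth.read_genotypes_tsv(outdir / gfile)
        keep = [i for i, s in enumerate(geno.sample_ids) if s in ids]
        geno = synth.GenotypeMatrix(
            sample_ids=[geno.sample_ids[i] for i in keep],
            variant_ids=geno.variant_ids,
            dosage=geno.dosage[keep],
        )
        aligned, report = grs_mod.harmonize(
            weights, grs_mod.genotype_meta_from_variants(weights)
        )
        mode = "weighted" if trait.weighted_grs else "unweighted"
        vec = grs_mod.compute_grs(geno, aligned, mode=mode, trait=trait.name)
        group = grs_mod.dichotomize_at_median(vec.score)
        order = {s: k for k, s in enumerate(geno.sample_ids)}
        assert [s for s in geno.sample_ids] == list(
            cohort["sample_id"].astype(str)
        ), "genotype/cohort sample order mismatch"
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": geno.sample_ids,
                    "trait": trait.name,
                    "score": vec.score,
                    "group": group,
                }
            )
        )
        strength = grs_mod.instrument_strength(
            cohort[trait.name].to_numpy(float), vec.score
        )
        strength_rows.append(
            {
                "trait": trait.name,
                "mode": mode,
                "n_variants_used": vec.n_variants_used,
                "n_dropped": report.n_input - report.n_used,
                "r2": strength.r2,
                "f_stat": strength.f_stat,
                "n": strength.n,
            }
        )
    _write_table(pd.concat(rows, ignore_index=True),
                 outdir / "grs.csv", cfg)
    _write_table(pd.DataFrame(strength_rows),
                 outdir / "instrument_strength.csv", cfg)
    return {"traits": [r["trait"] for r in strength_rows]}


def _grs_wide(outdir: Path) -> pd.DataFrame:
    grs = read_table(outdir / "grs.csv")
    return grs.pivot(index="sample_id", columns="trait", values="score")


def stage_onesample(cfg: RunConfig, outdir: Path) -> dict:
    cohort = _load_analysis_set(cfg, outdir)
    wide = _grs_wide(outdir)
    rows = []
    for trait in (cfg.trait_a, cfg.trait_b):
        g = wide.loc[cohort["sample_id"], trait.name].to_numpy(float)
        est = tsps_cox(
            cohort,
            exposure_name=trait.name,
            grs=g,
            covariates=cfg.covariates,
            exposure_kind=(
                "continuous" if trait.kind == "continuous" else "binary"
            ),
            scale_doubling=trait.scale_doubling,
            n_boot=cfg.n_boot,
            seed=stage_seed(cfg.seed, f"onesample:{trait.name}"),
        )
        row = est.summary_row()
        row["trait"] = trait.name
        rows.append(row)
    _write_table(pd.DataFrame(rows), outdir / "onesample.csv", cfg)
    return {"n_traits": len(rows)}


def stage_factorial(cfg: RunConfig, outdir: Path) -> dict:
    cohort = _load_analysis_set(cfg, outdir)
    wide = _grs_wide(outdir)
    ga = wide.loc[cohort["sample_id"], cfg.trait_a.name].to_numpy(float)
    gb = wide.loc[cohort["sample_id"], cfg.trait_b.name].to_numpy(float)
    res = fmr.factorial_mr(cohort, ga, gb, covariates=cfg.covariates)
    tab = res.summary()
    tab.insert(0, "pair", f"{cfg.trait_a.name}x{cfg.trait_b.name}")
    cont = fmr.continuous_factorial_cox(
        cohort, ga, gb, covariates=cfg.covariates
    )
    cont_rows = []
    for term in ("a", "b", "product"):
        lo, hi = cont["ci"][term]
        cont_rows.append(
            {
                "pair": f"{cfg.trait_a.name}x{cfg.trait_b.name}",
                "term": term,
                "hr_per_sd": cont["hr"][term],
                "ci_low": lo,
                "ci_high": hi,
                "reri": cont["reri"],
            }
        )
    _write_table(tab, outdir / "factorial.csv", cfg)
    _write_table(pd.DataFrame(cont_rows),
                 outdir / "factorial_continuous.csv", cfg)
    return {"reri_2x2": res.reri, "reri_continuous": cont["reri"]}


def stage_sensitivity(cfg: RunConfig, outdir: Path) -> dict:
    cohort = _load_analysis_set(cfg, outdir)
    ids = set(cohort["sample_id"].astype(str))
    geno = synth.read_genotypes_tsv(outdir / "genotypes_a.tsv")
    keep = [i for i, s in enumerate(geno.sample_ids) if s in ids]
    geno = synth.GenotypeMatrix(
        sample_ids=[geno.sample_ids[i] for i in keep],
        variant_ids=geno.variant_ids,
        dosage=geno.dosage[keep],
    )
    trait = cfg.trait_a
    assoc = sens.per_snp_associations(
        cohort, geno, trait.name, covariates=cfg.covariates,
        exposure_kind=(
            "continuous" if trait.kind == "continuous" else "binary"
        ),
    )
    sens.write_assoc_tsv(assoc, outdir / "snp_associations.tsv")
    sseed = stage_seed(cfg.seed, "sensitivity")
    est_rows = [
        sens.ivw(assoc).summary_row(),
        sens.weighted_median(assoc, "simple", seed=sseed).summary_row(),
        sens.weighted_median(assoc, "weighted", seed=sseed).summary_row(),
        sens.weighted_mode(assoc, seed=sseed).summary_row(),
    ]
    egger = sens.mr_egger(assoc)
    est_rows.append(
        {
            "method": "mr_egger",
            "beta": egger["slope"],
            "se": egger["se_slope"],
            "hr": float(np.exp(egger["slope"])),
            "ci_low": float(np.exp(egger["slope_ci"][0])),
            "ci_high": float(np.exp(egger["slope_ci"][1])),
            "n": egger["n_used"],
        }
    )
    est = pd.DataFrame(est_rows)
    est.insert(0, "trait", trait.name)
    est["egger_intercept"] = np.where(
        est["method"] == "mr_egger", egger["intercept"], np.nan
    )
    _write_table(est, outdir / "sensitivity.csv", cfg)

    wide = _grs_wide(outdir)
    grs_table = wide.loc[cohort["sample_id"]].reset_index(drop=True)
    cov_cols = [c for c in cfg.covariates if c in cohort.columns]
    scan = sens.confounder_scan(grs_table, cohort[cov_cols])
    _write_table(scan, outdir / "confounder_scan.csv", cfg)

    ph = sens.ph_schoenfeld_test(
        cohort.assign(_grs=grs_table[trait.name].to_numpy(float)),
        ["_grs"] + cov_cols,
    )
    _write_table(ph, outdir / "ph_test.csv", cfg)
    return {"n_variants": len(assoc)}


STAGES = {
    "simulate": stage_simulate,
    "grs": stage_grs,
    "onesample": stage_onesample,
    "factorial": stage_factorial,
    "sensitivity": stage_sensitivity,
}

STAGE_ORDER = ["simulate", "grs", "onesample", "factorial", "sensitivity"]


def run_pipeline(cfg: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the requested stages (default: all, in order)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages or STAGE_ORDER)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    meta = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "stages": {},
    }
    for name in STAGE_ORDER:
        if name not in stages:
            continue
        logger.info("running stage %s", name)
        meta["stages"][name] = STAGES[name](cfg, outdir)
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return meta
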
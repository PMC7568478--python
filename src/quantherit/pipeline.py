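"""End-to-end orchestration: adjust -> pairs -> sqreg -> h2 -> trend (-> remap).

A run is reproducible from (RunConfig, input files) alone; every stage
writes its artifact as plain CSV/JSON under the output directory and a
log records seeds, versions and per-stage record counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .family_structures import (
    build_full_sib,
    build_midparent,
    build_offspring_parent,
    spouse_correlation,
)
from .heritability import h2_curve
from .phenotype_adjustment import adjust_phenotypes, raw_exam_means
from .qq_remap import empirical_qf, group_difference, remap_curve
from .quantile_slopes import DEFAULT_TAUS, QuantileSlopeSet, sqreg
from .synthetic_cohort import Pedigree
from .trend_inference import trend_test

__all__ = ["RunConfig", "run_pipeline"]

SUMMARY_TAUS = (0.10, 0.25, 0.50, 0.75, 0.90)

RELATIONSHIP_BUILDERS = {
    "offspring_parent": build_offspring_parent,
    "offspring_midparent": build_midparent,
    "full_sib": build_full_sib,
}


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    input_dir: str
    output_dir: str
    taus: list | None = None
    B: int = 1000
    seed: int = 0
    dependent_adjusted: bool = True
    transform: str = "none"  # {"none", "log"} applied to raw values up front
    bootstrap_unit: str = "family"
    engine: str = "mm"
    relationships: tuple = ("offspring_parent", "offspring_midparent", "full_sib")
    r_spouse: float | None = None  # None -> estimate from the data
    sex_compare: bool = False

    def validate(self) -> None:
        if self.transform not in ("none", "log"):
            raise ValidationError("transform must be 'none' or 'log'")
        unknown = set(self.relationships) - set(RELATIONSHIP_BUILDERS)
        if unknown:
            raise ValidationError(f"unknown relationships: {sorted(unknown)}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["relationships"] = list(d["relationships"])
        if d["taus"] is not None:
            d["taus"] = [float(t) for t in d["taus"]]
        if d["r_spouse"] is not None:
            d["r_spouse"] = float(d["r_spouse"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "relationships" in d:
            d["relationships"] = tuple(d["relationships"])
        return cls(**d)


def _write_slope_set(qs: QuantileSlopeSet, outdir: Path, stem: str) -> None:
    qs.to_frame().to_csv(outdir / f"{stem}_slopes.csv", index=False)
    np.savetxt(outdir / f"{stem}_vcov.csv", qs.vcov, delimiter=",")
    np.savetxt(outdir / f"{stem}_replicates.csv", qs.boot_replicates, delimiter=",")


def _fit_relationship(pedigree, adjusted, raw, relationship, cfg, taus, r_spouse, log):
    pairs = RELATIONSHIP_BUILDERS[relationship](
        pedigree,
        adjusted,
        dependent_adjusted=cfg.dependent_adjusted,
        raw_values=raw,
    )
    qs = sqreg(
        pairs,
        taus=taus,
        B=cfg.B,
        seed=cfg.seed,
        unit=cfg.bootstrap_unit,
        engine=cfg.engine,
    )
    curve = h2_curve(qs, relationship, r_spouse)
    slope_trend = trend_test(qs)
    h2_trend = trend_test(curve)
    log["stages"][relationship] = {
        "n_pairs": len(pairs),
        "n_families": pairs.n_families,
        "n_excluded": pairs.n_excluded,
        "df": pairs.df,
        "bootstrap_failures": qs.n_boot_failed,
    }
    return pairs, qs, curve, slope_trend, h2_trend


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    cfg.validate()
    indir = Path(cfg.input_dir)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "run_config.yaml")

    data = Pedigree.read(indir)
    pedigree, phenotypes = data.pedigree, data.phenotypes.copy()
    if cfg.transform == "log":
        if (phenotypes["value"] <= 0).any():
            raise ValidationError("log transform requires strictly positive values")
        phenotypes["value"] = np.log(phenotypes["value"])

    log: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "n_individuals": int(len(pedigree)),
        "n_phenotype_rows": int(len(phenotypes)),
        "stages": {},
    }

    adjusted = adjust_phenotypes(phenotypes, pedigree)
    adjusted.to_csv(outdir / "adjusted.csv", index=False)
    raw = raw_exam_means(phenotypes)

    r_spouse = (
        cfg.r_spouse
        if cfg.r_spouse is not None
        else spouse_correlation(pedigree, adjusted)
    )
    log["r_spouse"] = float(r_spouse)

    taus = np.asarray(cfg.taus, dtype=float) if cfg.taus else DEFAULT_TAUS

    summary_rows = []
    trends: dict = {}
    for relationship in cfg.relationships:
        pairs, qs, curve, slope_trend, h2_trend = _fit_relationship(
            pedigree, adjusted, raw, relationship, cfg, taus, r_spouse, log
        )
        stem = relationship
        pairs.write(outdir / f"pairs_{stem}.csv")
        _write_slope_set(qs, outdir, stem)
        curve.to_frame().to_csv(outdir / f"h2_{stem}.csv", index=False)
        trends[relationship] = {
            "slope_scale": slope_trend.to_dict(),
            "h2_scale": h2_trend.to_dict(),
        }
        for tau in SUMMARY_TAUS:
            i = curve.tau_index(tau)
            summary_rows.append(
                {
                    "relationship": relationship,
                    "tau": tau,
                    "slope": round(float(qs.slopes[i]), 10),
                    "slope_se": round(float(qs.boot_se[i]), 10),
                    "h2": round(float(curve.h2[i]), 10),
                    "h2_se": round(float(curve.se[i]), 10),
                    "p_linear": slope_trend["linear"]["p"],
                }
            )

    (outdir / "trend.json").write_text(json.dumps(trends, indent=2))
    pd.DataFrame(summary_rows).to_csv(outdir / "summary.csv", index=False)

    if cfg.sex_compare:
        _sex_comparison(pedigree, phenotypes, adjusted, raw, cfg, taus, r_spouse, outdir, log)

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return outdir


def _sex_comparison(pedigree, phenotypes, adjusted, raw, cfg, taus, r_spouse, outdir, log):
    """Sex-stratified offspring-parent fits plus Q-Q remap onto the
    combined unadjusted offspring distribution."""
    is_off = pedigree["father_id"].notna() | pedigree["mother_id"].notna()
    fits = {}
    for sex in ("M", "F"):
        keep = pedigree.loc[~is_off | (pedigree["sex"] == sex)]
        pairs = build_offspring_parent(
            keep,
            adjusted,
            dependent_adjusted=cfg.dependent_adjusted,
            raw_values=raw,
        )
        qs = sqreg(
            pairs,
            taus=taus,
            B=cfg.B,
            seed=cfg.seed + (1 if sex == "F" else 2),
            unit=cfg.bootstrap_unit,
            engine=cfg.engine,
        )
        off_ids = set(pedigree.loc[is_off & (pedigree["sex"] == sex), "individual_id"])
        raw_off = phenotypes.loc[phenotypes["individual_id"].isin(off_ids), "value"]
        fits[sex] = (qs, empirical_qf(raw_off))
        log["stages"][f"offspring_parent_{sex}"] = {
            "n_pairs": len(pairs),
            "df": pairs.df,
        }

    all_off = set(pedigree.loc[is_off, "individual_id"])
    ref_qf = empirical_qf(
        phenotypes.loc[phenotypes["individual_id"].isin(all_off), "value"]
    )
    qs_m, qf_m = fits["M"]
    qs_f, qf_f = fits["F"]

    frames = []
    remapped = {}
    for sex, (qs, qf) in fits.items():
        rc = remap_curve(
            qs.taus, qs.slopes, qf, ref_qf, replicates=qs.boot_replicates
        )
        remapped[sex] = rc
        frames.append(rc.to_frame(group=sex))
    pd.concat(frames, ignore_index=True).to_csv(outdir / "remapped.csv", index=False)

    diff_pct = group_difference(
        qs_m.taus, qs_m.slopes, qs_f.taus, qs_f.slopes,
        qs_m.boot_replicates, qs_f.boot_replicates,
        qs_m.df, qs_f.df, matching="percentile",
    )
    rm, rf = remapped["M"], remapped["F"]
    diff_conc = group_difference(
        rm.ref_percentiles, rm.values, rf.ref_percentiles, rf.values,
        rm.replicates, rf.replicates,
        qs_m.df, qs_f.df, matching="concentration",
    )
    out = diff_pct.to_frame().assign(matching="percentile")
    out = pd.concat(
        [out, diff_conc.to_frame().assign(matching="concentration")],
        ignore_index=True,
    )
    out.to_csv(outdir / "sex_difference.csv", index=False)
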
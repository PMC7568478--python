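"""Nuclear-family cohort generator with known latent genetics.

The latent phenotype is built from an additive polygenic model on a
standardised scale:

* parents' latent phenotypes (P_f, P_m) are standard bivariate normal
  with the target spouse correlation;
* parental genetic values are G = h2*P + N(0, h2*(1-h2)), so that
  Var(G) = h2 and Cov(G, P) = h2;
* offspring genetic values are (G_f + G_m)/2 plus Mendelian segregation
  noise N(0, h2/2);
* offspring latent phenotypes add a sibship-shared component with
  variance c2 and residual environment with variance 1 - h2 - c2.

Observed per-exam values are ``transform(latent) + age/sex polynomial +
exam noise``.  With the identity transform every downstream
quantile-specific slope is flat in tau; a strictly convex transform
(``exp``) makes the raw-scale slopes increase with the quantile, which
is the effect the analysis pipeline is designed to detect.

Closed-form expectations under this model (used by the tests):
offspring-single-parent slope = h2*(1 + r_spouse)/2, offspring-midparent
slope = h2, full-sib slope/correlation = h2/2 + r_spouse*h2^2/2 + c2 —
exactly the values the Falconer transforms invert.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .quantile_slopes import _qreg_mm

__all__ = [
    "CohortConfig",
    "Pedigree",
    "generate_cohort",
    "expected_quantile_slope_oracle",
    "generate_concentration_law_groups",
    "TRANSFORMS",
]

TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda z: z,
    "exp": np.exp,
}


def _default_sibship_dist() -> tuple:
    # truncated geometric on {1..5}; the real sibship-size law is unknown
    p = 0.45
    w = np.array([(1 - p) ** (k - 1) * p for k in range(1, 6)])
    return tuple(w / w.sum())


@dataclass
class CohortConfig:
    """Generator parameters; see module docstring for the latent model.

    ``age_model`` holds the observed-scale coefficients
    (intercept, sex_effect, age_slope, age_quadratic, sex_age, sex_age2)
    applied as intercept + sex_effect*female + age_slope*age +
    age_quadratic*age^2 + sex_age*female*age + sex_age2*female*age^2.
    ``age_dist`` is (parent_mean, parent_sd, offspring_mean, offspring_sd).
    """

    n_families: int = 1000
    sibship_size_dist: Sequence[float] = field(default_factory=_default_sibship_dist)
    p_both_parents: float = 0.5
    r_spouse_target: float = 0.04
    h2_latent: float = 0.5
    c2_shared: float = 0.0
    transform: str | Callable = "identity"
    age_model: Sequence[float] = (0.0, 1.5, 0.04, -3e-4, 0.01, -1e-4)
    age_dist: Sequence[float] = (60.0, 9.0, 40.0, 9.0)
    sex_ratio: float = 0.5
    n_exams: int = 2
    exam_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1:
            raise ValidationError("n_families must be a positive integer")
        dist = np.asarray(self.sibship_size_dist, dtype=float)
        if dist.ndim != 1 or dist.size < 1:
            raise ValidationError("sibship_size_dist must be a 1-d probability vector")
        if np.any(dist < 0) or not np.isclose(dist.sum(), 1.0, atol=1e-8):
            raise ValidationError("sibship_size_dist must be nonnegative and sum to 1")
        if not 0.0 <= self.p_both_parents <= 1.0:
            raise ValidationError("p_both_parents must be in [0, 1]")
        if not -1.0 < self.r_spouse_target < 1.0:
            raise ValidationError("r_spouse_target must be in (-1, 1)")
        if not 0.0 <= self.h2_latent <= 1.0 or not 0.0 <= self.c2_shared <= 1.0:
            raise ValidationError("h2_latent and c2_shared must be in [0, 1]")
        if self.h2_latent + self.c2_shared > 1.0 + 1e-12:
            raise ValidationError(
                "impossible variance decomposition: h2_latent + c2_shared > 1"
            )
        if not 0.0 < self.sex_ratio < 1.0:
            raise ValidationError("sex_ratio must be in (0, 1)")
        if self.n_exams < 1:
            raise ValidationError("n_exams must be >= 1")
        if self.exam_noise_sd < 0:
            raise ValidationError("exam_noise_sd must be nonnegative")
        if len(tuple(self.age_model)) != 6:
            raise ValidationError("age_model needs 6 coefficients")
        self._transform_fn()  # raises on unknown names

    def _transform_fn(self) -> Callable[[np.ndarray], np.ndarray]:
        if callable(self.transform):
            return self.transform
        try:
            return TRANSFORMS[self.transform]
        except KeyError:
            raise ValidationError(
                f"unknown transform {self.transform!r}; "
                f"choose one of {sorted(TRANSFORMS)} or pass a callable"
            ) from None

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sibship_size_dist"] = [float(v) for v in d["sibship_size_dist"]]
        d["age_model"] = [float(v) for v in d["age_model"]]
        d["age_dist"] = [float(v) for v in d["age_dist"]]
        if callable(d["transform"]):
            raise ValidationError("cannot serialise a callable transform to YAML")
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class Pedigree:
    """Generated family tables.

    ``pedigree`` columns: individual_id, family_id, father_id, mother_id,
    sex, age, generation.  ``phenotypes`` columns: individual_id,
    exam_id, value.
    """

    pedigree: pd.DataFrame
    phenotypes: pd.DataFrame
    seed: int | None = None

    def write(self, outdir) -> None:
        """Write pedigree.csv and phenotypes.csv (seed in a comment header)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# seed={self.seed}\n" if self.seed is not None else ""
        for name, frame in (("pedigree", self.pedigree), ("phenotypes", self.phenotypes)):
            buf = io.StringIO()
            frame.to_csv(buf, index=False)
            (outdir / f"{name}.csv").write_text(header + buf.getvalue())

    @classmethod
    def read(cls, outdir) -> "Pedigree":
        outdir = Path(outdir)
        ped = pd.read_csv(outdir / "pedigree.csv", comment="#")
        pheno = pd.read_csv(outdir / "phenotypes.csv", comment="#")
        seed = None
        with open(outdir / "pedigree.csv") as fh:
            first = fh.readline()
            if first.startswith("# seed="):
                seed = int(first.strip().split("=", 1)[1])
        return cls(pedigree=ped, phenotypes=pheno, seed=seed)


def generate_cohort(config: CohortConfig) -> Pedigree:
    """Simulate a nuclear-family cohort; bit-reproducible given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    F = config.n_families
    h2, c2, r = config.h2_latent, config.c2_shared, config.r_spouse_target
    transform = config._transform_fn()

    # latent parent phenotypes with target spouse correlation
    z = rng.standard_normal((F, 2))
    p_f = z[:, 0]
    p_m = r * z[:, 0] + np.sqrt(1.0 - r * r) * z[:, 1]

    g_noise_sd = np.sqrt(h2 * (1.0 - h2))
    g_f = h2 * p_f + g_noise_sd * rng.standard_normal(F)
    g_m = h2 * p_m + g_noise_sd * rng.standard_normal(F)

    sizes = np.arange(1, len(tuple(config.sibship_size_dist)) + 1)
    k = rng.choice(sizes, size=F, p=np.asarray(config.sibship_size_dist, dtype=float))
    fam = np.repeat(np.arange(F), k)
    n_off = int(k.sum())

    g_o = (g_f + g_m)[fam] / 2.0 + np.sqrt(h2 / 2.0) * rng.standard_normal(n_off)
    c_fam = np.sqrt(c2) * rng.standard_normal(F)
    e_o = np.sqrt(max(1.0 - h2 - c2, 0.0)) * rng.standard_normal(n_off)
    p_o = g_o + c_fam[fam] + e_o

    parent_mu, parent_sd, off_mu, off_sd = config.age_dist
    age_f = np.clip(rng.normal(parent_mu, parent_sd, F), 18.0, None)
    age_m = np.clip(rng.normal(parent_mu, parent_sd, F), 18.0, None)
    age_o = np.clip(rng.normal(off_mu, off_sd, n_off), 18.0, None)
    sex_o = np.where(rng.random(n_off) < config.sex_ratio, "F", "M")

    fam_ids = np.char.add("FAM", np.arange(F).astype(str))
    father_ids = np.char.add(fam_ids, "_P1")
    mother_ids = np.char.add(fam_ids, "_P2")
    within = np.concatenate([np.arange(1, ki + 1) for ki in k]).astype(str)
    off_ids = np.char.add(np.char.add(fam_ids[fam], "_O"), within)

    pedigree = pd.DataFrame(
        {
            "individual_id": np.concatenate([father_ids, mother_ids, off_ids]),
            "family_id": np.concatenate([fam_ids, fam_ids, fam_ids[fam]]),
            "father_id": np.concatenate(
                [np.full(2 * F, np.nan, dtype=object), father_ids[fam]]
            ),
            "mother_id": np.concatenate(
                [np.full(2 * F, np.nan, dtype=object), mother_ids[fam]]
            ),
            "sex": np.concatenate([np.full(F, "M"), np.full(F, "F"), sex_o]),
            "age": np.concatenate([age_f, age_m, age_o]),
            "generation": ["parent"] * (2 * F) + ["offspring"] * n_off,
        }
    )

    latent = np.concatenate([p_f, p_m, p_o])
    female = (pedigree["sex"] == "F").to_numpy(dtype=float)
    age = pedigree["age"].to_numpy()
    b0, b_sex, b_age, b_age2, b_fa, b_fa2 = config.age_model
    age_part = (
        b0
        + b_sex * female
        + b_age * age
        + b_age2 * age**2
        + b_fa * female * age
        + b_fa2 * female * age**2
    )
    base = transform(latent) + age_part

    n_ind = base.size
    rows = []
    for exam in range(1, config.n_exams + 1):
        noise = (
            config.exam_noise_sd * rng.standard_normal(n_ind)
            if config.exam_noise_sd > 0
            else 0.0
        )
        rows.append(
            pd.DataFrame(
                {
                    "individual_id": pedigree["individual_id"],
                    "exam_id": exam,
                    "value": base + noise,
                }
            )
        )
    phenotypes = pd.concat(rows, ignore_index=True)

    # drop one random parent's phenotypes in single-parent families
    single = rng.random(F) >= config.p_both_parents
    drop_father = rng.random(F) < 0.5
    dropped = np.where(
        single & drop_father, father_ids, np.where(single, mother_ids, "")
    )
    dropped_ids = set(dropped[single])
    if dropped_ids:
        phenotypes = phenotypes[
            ~phenotypes["individual_id"].isin(dropped_ids)
        ].reset_index(drop=True)

    return Pedigree(pedigree=pedigree, phenotypes=phenotypes, seed=config.seed)


def expected_quantile_slope_oracle(
    rho: float,
    transform: str | Callable = "identity",
    tau: float = 0.5,
    n_oracle: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Brute-force Monte-Carlo oracle for the tau-quantile slope.

    Simulates ``n_oracle`` standard bivariate-normal pairs with
    correlation ``rho``, applies ``transform`` to both coordinates and
    fits a quantile regression of the transformed second coordinate on
    the transformed first.  Deterministic given ``seed``.  Independent
    of the cohort generator and of the pair-building machinery.
    """
    if not -1.0 < rho < 1.0:
        raise ValidationError("rho must be in (-1, 1)")
    if not 0.0 < tau < 1.0:
        raise ValidationError("tau must be in (0, 1)")
    if n_oracle < 100:
        raise ValidationError("n_oracle must be >= 100")
    fn = transform if callable(transform) else TRANSFORMS.get(transform)
    if fn is None:
        raise ValidationError(f"unknown transform {transform!r}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_oracle, 2))
    x = z[:, 0]
    y = rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1]
    tx, ty = fn(x), fn(y)
    ab = _qreg_mm(tx, ty, np.ones(n_oracle), np.array([tau]))
    return float(ab[1, 0])


def generate_concentration_law_groups(
    n_pairs: int = 6000,
    rho: float = 0.26,
    shift: float = 0.8,
    seed: int = 0,
) -> dict:
    """Two-group pair sample whose true slope law depends only on
    concentration.

    Pairs (parent, offspring) share one bivariate-normal latent law with
    correlation ``rho``; both coordinates are exponentiated and group
    "B"'s dependent values are additionally scaled by ``exp(shift)``.
    The conditional tau-quantile of the dependent given the predictor is
    then proportional to the dependent concentration itself, so the true
    local slope is one common linear function of concentration in both
    groups.  Because group membership is independent of the pair and
    only the dependent axis is rescaled, group B's fitted slope curve is
    exp(shift) times group A's at matched percentiles (clearly
    different), while both collapse onto the same curve when indexed by
    concentration — the pattern the Q-Q remap is designed to reveal.

    Returns a dict with per-group predictor/dependent arrays and the
    combined dependent sample (the Q-Q reference distribution).
    """
    if n_pairs < 100:
        raise ValidationError("n_pairs must be >= 100")
    if not -1.0 < rho < 1.0:
        raise ValidationError("rho must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_pairs, 2))
    x_lat = z[:, 0]
    y_lat = rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1]
    in_b = rng.random(n_pairs) < 0.5
    x = np.exp(x_lat)
    y = np.exp(y_lat + shift * in_b)
    return {
        "A": {"predictor": x[~in_b], "dependent": y[~in_b]},
        "B": {"predictor": x[in_b], "dependent": y[in_b]},
        "combined_dependent": y,
    }
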
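"""Synthetic herd, hematology, growth and RNA-seq count generator.

Emulates a forage-fed heifer feed-efficiency trial: 61 animals from 3 breeds
sired by 12 AI sires, penned in weight-stratified groups; a 15-parameter CBC
panel drawn to match published herd means/SDs while preserving the arithmetic
identities a hematology instrument guarantees (WBC equals the sum of the five
differential counts; MCHC = HGB/HCT × 100); serial body weights following a
quadratic growth curve with ADG/ADFI/G:F traits; and a gene × sample
negative-binomial count matrix with library-size variation, cell-composition
confounding, and a small set of planted trait-associated genes whose identity
is recorded for recovery scoring.

Every stage derives its own child seed from the master seed, so outputs are
reproducible yet stages remain decoupled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CBC_PARAMS",
    "DIFFERENTIAL_COUNTS",
    "simulate_herd",
    "simulate_cbc",
    "simulate_weights_and_intake",
    "simulate_counts",
    "simulate_all",
    "write_outputs",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


# canonical CBC parameter order (instrument panel order)
CBC_PARAMS = [
    "WBC", "NEU", "LYM", "MONO", "EOS", "BAS",
    "RBC", "HGB", "HCT", "MCV", "MCH", "MCHC", "RDW", "PLT", "MPV",
]
DIFFERENTIAL_COUNTS = ["NEU", "LYM", "MONO", "EOS", "BAS"]

# herd-level anchor moments: mean, SD per CBC parameter (instrument units)
DEFAULT_CBC_ANCHORS: dict[str, tuple[float, float]] = {
    "WBC": (9.56, 2.53),
    "NEU": (3.55, 1.75),
    "LYM": (5.24, 1.11),
    "MONO": (0.57, 0.19),
    "EOS": (0.11, 0.04),
    "BAS": (0.08, 0.03),
    "RBC": (9.21, 1.08),
    "HGB": (12.57, 1.19),
    "HCT": (37.31, 3.61),
    "MCV": (40.80, 3.74),
    "MCH": (13.73, 1.26),
    "MCHC": (33.69, 0.76),
    "RDW": (23.18, 1.38),
    "PLT": (641.77, 146.08),
    "MPV": (4.80, 0.35),
}

# trait anchors: mean, SD (ADG/ADFI in kg/d; G:F is derived, not drawn)
DEFAULT_TRAIT_ANCHORS: dict[str, tuple[float, float]] = {
    "ADG": (0.8, 0.2),
    "ADFI": (7.5, 1.2),
    "GF": (0.11, 0.03),
}

# mean body weight (kg) at the five weighing occasions of the 84-d trial
DEFAULT_WEIGHT_ANCHORS: dict[int, float] = {
    0: 283.0, 21: 306.5, 42: 315.2, 63: 333.5, 84: 347.4,
}

WEIGH_DAYS = (0, 1, 21, 42, 63, 84)


@dataclass
class SimConfig:
    """All knobs of the generator; defaults reproduce the trial conditions."""

    n_animals: int = 61
    n_breeds: int = 3
    n_sires: int = 12
    n_pens: int = 4
    seed: int = 0
    n_genes: int = 34000
    n_planted: int = 20
    planted_effect: float = 0.6      # target partial correlation with the trait
    confound_strength: float = 0.5   # SD of cell-composition effect on log-mean
    confound_frac: float = 0.3       # fraction of genes tied to composition
    nb_dispersion: float = 0.1       # variance = mu + dispersion * mu^2
    trait_anchors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_ANCHORS)
    )
    cbc_anchors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CBC_ANCHORS)
    )
    weight_anchors: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHT_ANCHORS)
    )
    # trait architecture
    sire_variance: float = 0.01      # ADG-scale sire variance (kg/d)^2
    cbc_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    # growth-curve details
    age_mean: float = 270.0          # days at d 0 (~9 months)
    age_sd: float = 15.0
    weight_noise_sd: float = 3.0     # kg, scale-level measurement noise
    curvature: float | None = None   # kg/d^2; None = fit from weight anchors
    # library-size variation (lognormal sigma of per-sample factors)
    libsize_sigma: float = 0.25
    # trait the planted genes track
    planted_trait: str = "GF"

    def validate(self) -> None:
        if min(self.n_animals, self.n_breeds, self.n_sires, self.n_pens) < 1:
            raise ConfigurationError("counts must be positive")
        if self.n_breeds > self.n_sires:
            raise ConfigurationError(
                f"cannot nest {self.n_sires} sires within {self.n_breeds} "
                "breeds: need n_breeds <= n_sires"
            )
        if self.n_sires > self.n_animals:
            raise ConfigurationError("n_sires must not exceed n_animals")
        if self.n_planted >= self.n_genes:
            raise ConfigurationError("n_planted must be < n_genes")
        if self.n_planted > 0 and not (0.0 < self.planted_effect < 1.0):
            raise ConfigurationError("planted_effect must lie in (0, 1)")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        for name, (_, sd) in {**self.trait_anchors, **self.cbc_anchors}.items():
            if sd < 0:
                raise ConfigurationError(f"anchor SD for {name} must be >= 0")
        for p in CBC_PARAMS:
            if p not in self.cbc_anchors:
                raise ConfigurationError(f"missing CBC anchor for {p}")


_STAGES = ["herd", "cbc", "weights", "counts"]


def _stage_rng(cfg: SimConfig, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(_STAGES.index(stage),))
    return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery scoring."""

    planted_gene_ids: list[str] = field(default_factory=list)
    planted_directions: dict[str, int] = field(default_factory=dict)
    confounded_gene_ids: list[str] = field(default_factory=list)
    confounded_components: dict[str, str] = field(default_factory=dict)
    true_sire_variance: float = 0.0
    true_cbc_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    true_adg: np.ndarray | None = None
    trait_noise: dict[str, np.ndarray] = field(default_factory=dict)
    sire_effects: dict[str, np.ndarray] = field(default_factory=dict)
    library_factors: np.ndarray | None = None

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x

        payload = {
            "planted_gene_ids": self.planted_gene_ids,
            "planted_directions": self.planted_directions,
            "confounded_gene_ids": self.confounded_gene_ids,
            "true_sire_variance": self.true_sire_variance,
            "true_cbc_effects": self.true_cbc_effects,
            "true_adg": conv(self.true_adg),
            "library_factors": conv(self.library_factors),
        }
        return json.dumps(payload, indent=1)


def _balanced_assignment(n: int, levels: list[str], rng: np.random.Generator) -> np.ndarray:
    """Assign n items to levels as evenly as possible (counts within +-1)."""
    reps = np.tile(levels, n // len(levels) + 1)[:n]
    return rng.permutation(reps)


def simulate_herd(cfg: SimConfig) -> pd.DataFrame:
    """Generate animal-level metadata: breed, sire nested in breed, pen, age.

    Sires are partitioned across breeds (each sire belongs to one breed, as
    in an AI breeding design) and animals inherit the breed of their sire;
    pens are assigned independently (weight stratification is emulated only
    through balanced allocation).  Factor level counts are balanced within
    one animal.
    """
    cfg.validate()
    rng = _stage_rng(cfg, "herd")
    sires = [f"S{i + 1:02d}" for i in range(cfg.n_sires)]
    breeds = [f"B{i + 1}" for i in range(cfg.n_breeds)]
    pens = [f"P{i + 1}" for i in range(cfg.n_pens)]
    # nest sires in breeds, balanced
    sire_breed = dict(zip(sires, np.tile(breeds, cfg.n_sires // cfg.n_breeds + 1)[: cfg.n_sires]))
    animal_sire = _balanced_assignment(cfg.n_animals, sires, rng)
    animal_breed = np.array([sire_breed[s] for s in animal_sire])
    animal_pen = _balanced_assignment(cfg.n_animals, pens, rng)
    age = np.round(rng.normal(cfg.age_mean, cfg.age_sd, cfg.n_animals))
    meta = pd.DataFrame(
        {
            "animal_id": [f"A{i + 1:03d}" for i in range(cfg.n_animals)],
            "breed": animal_breed,
            "pen": animal_pen,
            "sire": animal_sire,
            "age": age,
        }
    )
    return meta


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the requested mean and SD."""
    if mean <= 0:
        raise ConfigurationError("log-normal anchor mean must be > 0")
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def simulate_cbc(
    meta: pd.DataFrame, cfg: SimConfig, truth_out: GroundTruth
) -> pd.DataFrame:
    """Draw the 15-parameter CBC panel per animal.

    The five differential leukocyte counts are independent log-normals at
    their anchor moments and WBC is their exact row-wise sum.  (log RBC,
    log MCV) are bivariate normal with the negative correlation implied by
    the HCT anchor SD; HCT is derived as RBC·MCV/10 times an analytic
    calibration constant so its expectation matches the anchor mean exactly.
    MCHC is drawn at its anchor and HGB defined as MCHC·HCT/100, so the
    MCHC = HGB/HCT × 100 identity holds exactly; MCH = 10·HGB/RBC carries a
    calibration constant of a few permille, the instrument-level slack
    between the anchors.  RDW, PLT, MPV are independent log-normals.
    """
    cfg.validate()
    rng = _stage_rng(cfg, "cbc")
    n = len(meta)
    a = cfg.cbc_anchors
    out = pd.DataFrame(index=meta.index)

    def draw_ln(name: str, size: int) -> np.ndarray:
        mean, sd = a[name]
        if sd == 0:
            return np.full(size, mean)
        mu, sig = _lognormal_params(mean, sd)
        return np.exp(rng.normal(mu, sig, size))

    for p in DIFFERENTIAL_COUNTS:
        out[p] = draw_ln(p, n)
    out["WBC"] = out[DIFFERENTIAL_COUNTS].sum(axis=1)

    # correlated (log RBC, log MCV) so that Var(log HCT) matches the anchor
    m_r, s_r = a["RBC"]
    m_v, s_v = a["MCV"]
    m_h, s_h = a["HCT"]
    if s_r == 0 and s_v == 0:
        rbc = np.full(n, m_r)
        mcv = np.full(n, m_v)
        cov_term = 0.0
    else:
        mu_r, sg_r = _lognormal_params(m_r, s_r) if s_r > 0 else (np.log(m_r), 0.0)
        mu_v, sg_v = _lognormal_params(m_v, s_v) if s_v > 0 else (np.log(m_v), 0.0)
        v_h = np.log1p((s_h / m_h) ** 2) if s_h > 0 else 0.0
        if sg_r > 0 and sg_v > 0:
            rho = (v_h - sg_r**2 - sg_v**2) / (2.0 * sg_r * sg_v)
            rho = float(np.clip(rho, -0.95, 0.95))
        else:
            rho = 0.0
        cov = np.array(
            [[sg_r**2, rho * sg_r * sg_v], [rho * sg_r * sg_v, sg_v**2]]
        )
        logs = rng.multivariate_normal([mu_r, mu_v], cov, size=n)
        rbc, mcv = np.exp(logs[:, 0]), np.exp(logs[:, 1])
        cov_term = rho * sg_r * sg_v
    # E[RBC*MCV] = m_r*m_v*exp(cov_term); kappa recenters HCT on its anchor
    kappa_hct = m_h / (m_r * m_v * np.exp(cov_term) / 10.0)
    hct = rbc * mcv / 10.0 * kappa_hct

    m_c, s_c = a["MCHC"]
    mchc = draw_ln("MCHC", n)
    hgb = mchc * hct / 100.0
    # 10*HGB/RBC = MCHC*kappa_hct*MCV/100 exactly (RBC cancels), so
    # E[MCH] = E[MCHC]*kappa_hct*E[MCV]/100 for independent MCHC
    m_mch = a["MCH"][0]
    kappa_mch = m_mch / (m_c * kappa_hct * m_v / 100.0)
    mch = 10.0 * hgb / rbc * kappa_mch

    out["RBC"] = rbc
    out["HGB"] = hgb
    out["HCT"] = hct
    out["MCV"] = mcv
    out["MCH"] = mch
    out["MCHC"] = mchc
    for p in ("RDW", "PLT", "MPV"):
        out[p] = draw_ln(p, n)
    out = out[CBC_PARAMS]
    out.insert(0, "animal_id", meta["animal_id"].to_numpy())
    if (out[CBC_PARAMS].to_numpy() < 0).any():
        raise RuntimeError("negative CBC value generated")  # pragma: no cover
    return out


def _fit_curvature(cfg: SimConfig) -> float:
    days = np.array(sorted(cfg.weight_anchors))
    w = np.array([cfg.weight_anchors[d] for d in days])
    return float(np.polyfit(days, w, 2)[0])


def simulate_weights_and_intake(
    meta: pd.DataFrame,
    cfg: SimConfig,
    truth_out: GroundTruth,
    cbc: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate serial body weights plus ADG / ADFI / G:F traits.

    Each animal's latent growth is quadratic, BW(d) = w0 + b·d + c·d², with
    shared curvature c fitted to the herd mean weights and per-animal slope
    chosen so the latent 84-d gain equals 84·ADG.  Latent ADG carries a sire
    effect (variance ``cfg.sire_variance``), linear CBC effects from
    ``cfg.cbc_effects`` and residual noise scaled so the total variance hits
    the anchor SD².  G:F is defined per animal as ADG/ADFI.  Returns
    ``(weights long-format, traits)``.
    """
    cfg.validate()
    rng = _stage_rng(cfg, "weights")
    n = len(meta)
    sires = sorted(meta["sire"].unique())
    sire_idx = meta["sire"].map({s: i for i, s in enumerate(sires)}).to_numpy()

    for effects in cfg.cbc_effects.values():
        for pname in effects:
            if pname not in CBC_PARAMS:
                raise ConfigurationError(f"unknown CBC parameter '{pname}'")
    cbc_panel = cbc

    def trait_vector(name: str, sire_scale: float) -> np.ndarray:
        mean, sd = cfg.trait_anchors[name]
        s2_sire = cfg.sire_variance * sire_scale
        if s2_sire > 0:
            u = rng.normal(0.0, np.sqrt(s2_sire), len(sires))
            u -= u.mean()  # deviations from the herd mean, so E[trait] is exact
        else:
            u = np.zeros(len(sires))
        contrib = np.zeros(n)
        var_cbc = 0.0
        for pname, slope in cfg.cbc_effects.get(name, {}).items():
            if cbc_panel is None:
                raise ConfigurationError(
                    "cbc_effects set but no CBC panel supplied; pass the "
                    "simulate_cbc output (simulate_all handles the ordering)"
                )
            col = cbc_panel[pname].to_numpy(float)
            contrib += slope * (col - col.mean())
            var_cbc += slope**2 * col.var()
        s2_e = max(sd**2 - s2_sire - var_cbc, (0.05 * sd) ** 2 if sd > 0 else 0.0)
        noise = rng.normal(0.0, np.sqrt(s2_e), n) if s2_e > 0 else np.zeros(n)
        truth_out.sire_effects[name] = u
        truth_out.trait_noise[name] = noise
        return mean + u[sire_idx] + contrib + noise

    adg = trait_vector("ADG", 1.0)
    # ADFI sire variance scaled to keep the same intraclass share as ADG
    adg_sd = cfg.trait_anchors["ADG"][1]
    adfi_sd = cfg.trait_anchors["ADFI"][1]
    scale = (adfi_sd / adg_sd) ** 2 if adg_sd > 0 else 0.0
    adfi = trait_vector("ADFI", scale)
    adfi = np.maximum(adfi, 0.1)
    gf = adg / adfi

    c = cfg.curvature if cfg.curvature is not None else _fit_curvature(cfg)
    w0_mean = cfg.weight_anchors[min(cfg.weight_anchors)]
    w0 = rng.normal(w0_mean, 27.3, n)
    b = adg - 84.0 * c  # so that f(84) - f(0) = 84 * ADG exactly
    rows = []
    for d in WEIGH_DAYS:
        noise = (
            rng.normal(0.0, cfg.weight_noise_sd, n)
            if cfg.weight_noise_sd > 0
            else np.zeros(n)
        )
        bw = w0 + b * d + c * d**2 + noise
        rows.append(
            pd.DataFrame(
                {"animal_id": meta["animal_id"], "day": d, "weight_kg": bw}
            )
        )
    weights = pd.concat(rows, ignore_index=True)

    traits = pd.DataFrame(
        {
            "animal_id": meta["animal_id"].to_numpy(),
            "ADG": adg,
            "ADFI": adfi,
            "GF": gf,
        }
    )
    truth_out.true_adg = adg.copy()
    truth_out.true_sire_variance = cfg.sire_variance
    truth_out.true_cbc_effects = {k: dict(v) for k, v in cfg.cbc_effects.items()}
    return weights, traits


def simulate_counts(
    meta: pd.DataFrame,
    cbc: pd.DataFrame,
    traits: pd.DataFrame,
    cfg: SimConfig,
    truth_out: GroundTruth,
) -> pd.DataFrame:
    """Simulate the gene × sample count matrix.

    Generative model on the natural-log scale per gene g, sample s:

        log mu_gs = base_g + log(sf_s) + gamma_g · comp_s + delta_g · t_s

    where ``sf_s`` are log-normal library-size factors, ``comp_s`` is a
    standardised cell-composition score of the sample (one of the five
    leukocyte fractions or RBC, chosen per confounded gene), and ``t_s`` is
    the standardised design-independent component of the target trait.
    ``delta_g`` is calibrated per planted gene so the partial correlation of
    residualised log counts with the residualised trait targets
    ``cfg.planted_effect`` given the gene's Poisson + overdispersion noise.
    Counts are negative binomial with variance mu + dispersion·mu²;
    dispersion 0 reduces to Poisson.
    """
    cfg.validate()
    if cfg.n_genes < 100:
        raise ConfigurationError("need n_genes >= 100")
    rng = _stage_rng(cfg, "counts")
    n = len(meta)
    G = cfg.n_genes
    gene_ids = np.array([f"G{i + 1:05d}" for i in range(G)])
    sample_ids = meta["animal_id"].to_numpy()

    # baseline log2 abundance ~ N(3, 2.5): ~45% of genes pass a mean>=10 filter
    base = np.log(2.0) * rng.normal(3.0, 2.5, G)
    sf = np.exp(rng.normal(0.0, cfg.libsize_sigma, n))
    sf /= np.exp(0.5 * cfg.libsize_sigma**2)  # mean ~1

    # composition scores: standardized leukocyte fractions + RBC
    wbc = cbc["WBC"].to_numpy(float)
    comp_cols = [cbc[p].to_numpy(float) / wbc for p in DIFFERENTIAL_COUNTS]
    comp_cols.append(cbc["RBC"].to_numpy(float))
    comp = np.column_stack(comp_cols)
    comp = (comp - comp.mean(0)) / np.where(comp.std(0) > 0, comp.std(0), 1.0)

    log_mu = base[:, None] + np.log(sf)[None, :]

    comp_names = [f"{p}_frac" for p in DIFFERENTIAL_COUNTS] + ["RBC"]
    n_conf = int(round(cfg.confound_frac * G))
    conf_idx = rng.choice(G, size=n_conf, replace=False) if n_conf else np.array([], int)
    which = np.array([], int)
    if n_conf and cfg.confound_strength > 0:
        which = rng.integers(0, comp.shape[1], n_conf)
        gamma = rng.normal(0.0, cfg.confound_strength, n_conf)
        log_mu[conf_idx] += gamma[:, None] * comp[:, which].T

    planted_idx = np.array([], int)
    directions = np.array([], int)
    if cfg.n_planted > 0:
        # residual (design-independent) trait component drives planted genes.
        # For G:F the first-order residual combines both component-trait
        # noises: d(A/F) = (nA - (mA/mF) nF)/mF, evaluated at anchor means.
        tname = cfg.planted_trait
        if tname == "GF" and "ADG" in truth_out.trait_noise:
            n_adg = truth_out.trait_noise["ADG"]
            n_adfi = truth_out.trait_noise.get("ADFI", np.zeros(n))
            m_adg = cfg.trait_anchors["ADG"][0]
            m_adfi = cfg.trait_anchors["ADFI"][0]
            t_res = n_adg - (m_adg / m_adfi) * n_adfi
        else:
            t_res = truth_out.trait_noise.get(tname)
        if t_res is None or t_res.std() == 0:
            t_res = traits[tname].to_numpy(float)
        t = (t_res - t_res.mean()) / t_res.std()
        # plant among high-expression genes so counting noise stays small
        eligible = np.setdiff1d(np.where(base >= np.log(50.0))[0], conf_idx)
        if len(eligible) < cfg.n_planted:
            raise ConfigurationError("too few high-expression genes to plant")
        planted_idx = rng.choice(eligible, size=cfg.n_planted, replace=False)
        directions = rng.choice([-1, 1], size=cfg.n_planted)
        r = cfg.planted_effect
        mu_g = np.exp(base[planted_idx])
        v_noise = 1.0 / mu_g + cfg.nb_dispersion  # delta-method Var(log count)
        delta = np.sqrt(v_noise * r**2 / (1.0 - r**2))
        log_mu[planted_idx] += (directions * delta)[:, None] * t[None, :]

    mu = np.exp(log_mu)
    if cfg.nb_dispersion == 0:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / cfg.nb_dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)

    truth_out.planted_gene_ids = list(gene_ids[planted_idx])
    truth_out.planted_directions = dict(
        zip(gene_ids[planted_idx], (int(x) for x in directions))
    )
    truth_out.confounded_gene_ids = list(gene_ids[np.sort(conf_idx)])
    if len(which):
        truth_out.confounded_components = {
            gene_ids[g]: comp_names[w] for g, w in zip(conf_idx, which)
        }
    truth_out.library_factors = sf
    cm = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    cm.index.name = "gene_id"
    return cm


def simulate_all(cfg: SimConfig) -> dict[str, object]:
    """Run every stage in order; returns a dict of tables plus ground truth."""
    truth = GroundTruth()
    meta = simulate_herd(cfg)
    cbc = simulate_cbc(meta, cfg, truth)
    weights, traits = simulate_weights_and_intake(meta, cfg, truth, cbc=cbc)
    counts = simulate_counts(meta, cbc, traits, cfg, truth)
    return {
        "meta": meta,
        "cbc": cbc,
        "weights": weights,
        "traits": traits,
        "counts": counts,
        "truth": truth,
    }


def write_outputs(bundle: dict[str, object], outdir: str | Path) -> dict[str, Path]:
    """Write all simulated tables: counts TSV, CSVs, ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "meta": outdir / "metadata.csv",
        "cbc": outdir / "cbc.csv",
        "weights": outdir / "weights.csv",
        "traits": outdir / "traits.csv",
        "truth": outdir / "ground_truth.json",
    }
    bundle["counts"].to_csv(paths["counts"], sep="\t")
    bundle["meta"].to_csv(paths["meta"], index=False)
    bundle["cbc"].to_csv(paths["cbc"], index=False)
    bundle["weights"].to_csv(paths["weights"], index=False)
    bundle["traits"].to_csv(paths["traits"], index=False)
    paths["truth"].write_text(bundle["truth"].to_json())
    return paths
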
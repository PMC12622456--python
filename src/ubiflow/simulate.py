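"""Synthetic two-group proteome/ubiquitinome/clinical data with ground truth.

The generator emulates the study design the pipeline targets: two groups
(Ctrl vs a mechanical-unloading treatment) x 4 replicates, log-normal
intensities, detection-limit (left-censored) missingness, and four site
archetypes with known labels:

* ``degradative`` — site effect opposite in sign to a real protein effect
  (ubiquitylation driving turnover);
* ``non_degradative`` — independent site effect on a flat protein
  (signalling ubiquitylation);
* ``confounded`` — the site copies its differential protein's realised
  profile with no intrinsic effect, so the Spearman confound filter's
  removals are unambiguously right or wrong;
* ``null`` — flat site on a flat protein.

Ubiquitin's own remnant peptides get per-linkage multiplicative factors
(default: K63 up x2, K11 and K27 down x0.5, K48 and the rest flat), and
planted E3/DUB enzymes are wired to substrate sites with catalysis-
consistent directions so the interaction-mapping stage has a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    LINKAGE_POSITIONS,
    AbundanceMatrix,
    EsiLibrary,
    ClinicalCohort,
    SampleDesign,
    SiteAnnotation,
    annotations_frame,
)

__all__ = [
    "OmicsSimConfig",
    "SimTruth",
    "generate_omics",
    "generate_esi_library",
    "generate_clinical",
    "default_design",
]

UBIQUITIN_ID = "UBB"

DEFAULT_LINKAGE_EFFECTS: dict[str, float] = {
    "K6": 1.0,
    "K11": 0.5,
    "K27": 0.5,
    "K29": 1.0,
    "K33": 1.0,
    "K48": 1.0,
    "K63": 2.0,
}


@dataclass(frozen=True)
class OmicsSimConfig:
    """Study-design parameters for the omics simulator.

    Effects are additive on the log2 scale; noise_sd_log2 is the
    replicate-to-replicate SD.  fraction_* are site-archetype fractions
    (remainder = null).  censor_quantile is the per-sample left-censoring
    point: raw intensities below that sample quantile become missing.
    """

    n_proteins: int = 300
    sites_per_protein_mean: float = 2.9
    n_per_group: int = 4
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 1.5
    protein_effect_log2: float = 1.0
    site_effect_log2: float = 2.0
    noise_sd_log2: float = 0.25
    fraction_degradative: float = 0.05
    fraction_nondegradative: float = 0.15
    fraction_confounded: float = 0.05
    fraction_proteins_differential: float = 0.2
    confounded_noise_sd: float = 0.1
    censor_quantile: float = 0.05
    linkage_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LINKAGE_EFFECTS)
    )
    peptides_per_linkage: int = 3
    n_true_esi_pairs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (
            self.fraction_degradative
            + self.fraction_nondegradative
            + self.fraction_confounded
        )
        if fr > 1.0:
            raise ValueError(f"archetype fractions sum to {fr} > 1")
        if min(
            self.fraction_degradative,
            self.fraction_nondegradative,
            self.fraction_confounded,
        ) < 0:
            raise ValueError("archetype fractions must be >= 0")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.noise_sd_log2 <= 0 or self.baseline_log2_sd <= 0:
            raise ValueError("SDs must be positive")
        if not (0.0 <= self.censor_quantile < 1.0):
            raise ValueError("censor_quantile must lie in [0, 1)")


@dataclass
class SimTruth:
    """Planted ground truth, serialisable alongside the data."""

    protein_effects: pd.Series  # log2 effect per protein (0 = flat)
    site_archetypes: pd.DataFrame  # index site_id: protein_id, archetype, site_effect
    linkage_truth: pd.DataFrame  # linkage, factor, direction
    esi_truth: pd.DataFrame  # enzyme_id, enzyme_class, substrate_id, site_id
    enzyme_classes: pd.DataFrame  # enzyme_id, enzyme_class

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "truth_proteins": self.protein_effects.rename("log2_effect")
            .rename_axis("protein_id")
            .reset_index(),
            "truth_sites": self.site_archetypes.rename_axis("site_id").reset_index(),
            "truth_linkages": self.linkage_truth,
            "truth_esi": self.esi_truth,
            "enzyme_classes": self.enzyme_classes,
        }


def default_design(
    n_per_group: int = 4, groups: tuple[str, str] = ("Ctrl", "HLU")
) -> SampleDesign:
    samples = [f"{g}_{i + 1}" for g in groups for i in range(n_per_group)]
    return SampleDesign(
        tuple(samples), {s: s.rsplit("_", 1)[0] for s in samples}, groups
    )


def _censor(log2_values: pd.DataFrame, q: float, scale_to_raw: bool = True) -> pd.DataFrame:
    """Left-censor at each sample's q-quantile, on the linear scale."""
    raw = np.power(2.0, log2_values) if scale_to_raw else log2_values.copy()
    if q > 0:
        thresh = raw.quantile(q, axis=0)
        raw = raw.mask(raw.lt(thresh, axis=1))
    return raw


def generate_omics(
    config: OmicsSimConfig | None = None,
) -> tuple[AbundanceMatrix, AbundanceMatrix, list[SiteAnnotation], SimTruth, SampleDesign]:
    """Generate (proteome, ubiquitinome, annotations, truth, design).

    Both matrices are raw-scale (linear intensities) with censoring-induced
    missingness, ready for the preprocessing stage.  Identical config
    (including seed) gives bit-identical output.
    """
    config = config or OmicsSimConfig()
    rng = np.random.default_rng(config.seed)
    design = default_design(config.n_per_group)
    n_samp = 2 * config.n_per_group
    treat = np.array(
        [1.0 if design.group_of[s] == design.group_order[1] else 0.0 for s in design.sample_ids]
    )

    # --- proteins ---------------------------------------------------------
    protein_ids = [f"P{i:04d}" for i in range(1, config.n_proteins + 1)]
    n_eff = max(1, round(config.fraction_proteins_differential * config.n_proteins))
    eff_signs = rng.choice([-1.0, 1.0], size=n_eff)
    effects = np.zeros(config.n_proteins)
    effects[:n_eff] = eff_signs * config.protein_effect_log2
    protein_effects = pd.Series(effects, index=protein_ids)

    baselines = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_proteins)
    noise = rng.normal(0.0, config.noise_sd_log2, size=(config.n_proteins, n_samp))
    prot_log2 = baselines[:, None] + np.outer(effects, treat) + noise
    prot_df = pd.DataFrame(prot_log2, index=protein_ids, columns=design.sample_ids)

    # --- sites ------------------------------------------------------------
    n_sites = round(config.n_proteins * config.sites_per_protein_mean)
    n_deg = round(config.fraction_degradative * n_sites)
    n_conf = round(config.fraction_confounded * n_sites)
    n_nondeg = round(config.fraction_nondegradative * n_sites)
    n_null = n_sites - n_deg - n_conf - n_nondeg

    eff_pool = protein_ids[:n_eff]
    flat_pool = protein_ids[n_eff:]
    if (n_deg or n_conf) and not eff_pool:
        raise ValueError("degradative/confounded sites require differential proteins")
    if (n_nondeg or n_null) and not flat_pool:
        raise ValueError("non-degradative/null sites require flat proteins")

    annotations: list[SiteAnnotation] = []
    arch_rows = []
    site_profiles = []
    used_positions: dict[str, set[int]] = {}

    def _new_site(parent: str) -> str:
        taken = used_positions.setdefault(parent, set())
        while True:
            pos = int(rng.integers(1, 801))
            if pos not in taken:
                taken.add(pos)
                return f"{parent}_K{pos}", pos  # type: ignore[return-value]

    def _add_site(parent: str, archetype: str, profile: np.ndarray, eff: float) -> None:
        site_id, pos = _new_site(parent)  # type: ignore[misc]
        annotations.append(SiteAnnotation(site_id, parent, pos, False))
        arch_rows.append(
            {"site_id": site_id, "protein_id": parent, "archetype": archetype, "site_effect": eff}
        )
        site_profiles.append(profile)

    def _baseline() -> float:
        return float(rng.normal(config.baseline_log2_mean, config.baseline_log2_sd))

    for _ in range(n_deg):
        parent = eff_pool[int(rng.integers(len(eff_pool)))]
        eff = -np.sign(protein_effects[parent]) * config.site_effect_log2
        prof = _baseline() + eff * treat + rng.normal(0, config.noise_sd_log2, n_samp)
        _add_site(parent, "degradative", prof, float(eff))
    for _ in range(n_conf):
        parent = eff_pool[int(rng.integers(len(eff_pool)))]
        parent_prof = prot_df.loc[parent].to_numpy()
        prof = (
            _baseline()
            + (parent_prof - parent_prof.mean())
            + rng.normal(0, config.confounded_noise_sd, n_samp)
        )
        _add_site(parent, "confounded", prof, 0.0)
    for _ in range(n_nondeg):
        parent = flat_pool[int(rng.integers(len(flat_pool)))]
        eff = float(rng.choice([-1.0, 1.0])) * config.site_effect_log2
        prof = _baseline() + eff * treat + rng.normal(0, config.noise_sd_log2, n_samp)
        _add_site(parent, "non_degradative", prof, eff)
    for _ in range(n_null):
        parent = flat_pool[int(rng.integers(len(flat_pool)))]
        prof = _baseline() + rng.normal(0, config.noise_sd_log2, n_samp)
        _add_site(parent, "null", prof, 0.0)

    # --- ubiquitin linkage remnant peptides ------------------------------
    linkage_rows = []
    for pos in LINKAGE_POSITIONS:
        key = f"K{pos}"
        factor = float(config.linkage_effects.get(key, 1.0))
        eff = float(np.log2(factor))
        for k in range(config.peptides_per_linkage):
            suffix = "" if k == 0 else f".{k + 1}"
            site_id = f"{UBIQUITIN_ID}_{key}{suffix}"
            annotations.append(SiteAnnotation(site_id, UBIQUITIN_ID, pos, True))
            # remnant peptides are abundant but span a range (response
            # factors differ per peptide), not a degenerate top tail
            pep_base = float(
                rng.normal(config.baseline_log2_mean + 1.0, config.baseline_log2_sd)
            )
            prof = pep_base + eff * treat + rng.normal(0, config.noise_sd_log2, n_samp)
            arch_rows.append(
                {"site_id": site_id, "protein_id": UBIQUITIN_ID, "archetype": "linkage", "site_effect": eff}
            )
            site_profiles.append(prof)
        linkage_rows.append(
            {
                "linkage": key,
                "factor": factor,
                "direction": "up" if factor > 1 else ("down" if factor < 1 else "flat"),
            }
        )

    site_arch = pd.DataFrame(arch_rows).set_index("site_id")
    ubi_df = pd.DataFrame(
        np.vstack(site_profiles), index=site_arch.index, columns=design.sample_ids
    )

    # --- planted E3/DUB enzymes -------------------------------------------
    directional = site_arch[site_arch["archetype"].isin(["degradative", "non_degradative"])]
    n_pairs = min(config.n_true_esi_pairs, len(directional))
    chosen = rng.choice(len(directional), size=n_pairs, replace=False)
    esi_rows = []
    enz_rows = []
    enz_profiles = []
    enz_ids = []
    for i, idx in enumerate(sorted(chosen)):
        site_id = directional.index[idx]
        srow = directional.iloc[idx]
        site_sign = np.sign(srow["site_effect"])
        enz_class = "E3" if rng.random() < 0.5 else "DUB"
        enz_sign = site_sign if enz_class == "E3" else -site_sign
        enz_id = f"{enz_class}_{i + 1:03d}"
        enz_ids.append(enz_id)
        prof = (
            float(rng.normal(config.baseline_log2_mean, config.baseline_log2_sd))
            + enz_sign * config.protein_effect_log2 * treat
            + rng.normal(0, config.noise_sd_log2, n_samp)
        )
        enz_profiles.append(prof)
        esi_rows.append(
            {
                "enzyme_id": enz_id,
                "enzyme_class": enz_class,
                "substrate_id": srow["protein_id"],
                "site_id": site_id,
            }
        )
        enz_rows.append({"enzyme_id": enz_id, "enzyme_class": enz_class})
        protein_effects[enz_id] = enz_sign * config.protein_effect_log2
    if enz_ids:
        enz_df = pd.DataFrame(
            np.vstack(enz_profiles), index=enz_ids, columns=design.sample_ids
        )
        prot_df = pd.concat([prot_df, enz_df])

    proteome = AbundanceMatrix(_censor(prot_df, config.censor_quantile), scale="raw")
    ubiquitinome = AbundanceMatrix(_censor(ubi_df, config.censor_quantile), scale="raw")
    truth = SimTruth(
        protein_effects=protein_effects,
        site_archetypes=site_arch,
        linkage_truth=pd.DataFrame(linkage_rows),
        esi_truth=pd.DataFrame(
            esi_rows, columns=["enzyme_id", "enzyme_class", "substrate_id", "site_id"]
        ),
        enzyme_classes=pd.DataFrame(enz_rows, columns=["enzyme_id", "enzyme_class"]),
    )
    return proteome, ubiquitinome, annotations, truth, design


def generate_esi_library(
    truth: SimTruth,
    n_decoys: int = 40,
    true_confidence: tuple[float, float] = (0.8, 0.99),
    decoy_confidence: tuple[float, float] = (0.05, 0.4),
    seed: int = 0,
) -> EsiLibrary:
    """Library = planted true pairs (high confidence) + random decoys (low).

    Decoy (enzyme, substrate) pairs never duplicate a true pair; with zero
    decoys the library is exactly the truth.
    """
    rng = np.random.default_rng(seed)
    rows = []
    true_keys = set()
    for rec in truth.esi_truth.itertuples():
        conf = float(rng.uniform(*true_confidence))
        rows.append(
            {
                "enzyme_id": rec.enzyme_id,
                "enzyme_class": rec.enzyme_class,
                "substrate_id": rec.substrate_id,
                "confidence": conf,
            }
        )
        true_keys.add((rec.enzyme_id, rec.enzyme_class, rec.substrate_id))
    enzymes = truth.enzyme_classes
    substrates = truth.site_archetypes["protein_id"].unique().tolist()
    seen = set(true_keys)
    attempts = 0
    while len(rows) < len(true_keys) + n_decoys and attempts < 100 * (n_decoys + 1):
        attempts += 1
        if len(enzymes) == 0 or len(substrates) == 0:
            break
        e = enzymes.iloc[int(rng.integers(len(enzymes)))]
        s = substrates[int(rng.integers(len(substrates)))]
        key = (e["enzyme_id"], e["enzyme_class"], s)
        if key in seen:
            continue
        seen.add(key)
        rows.append(
            {
                "enzyme_id": key[0],
                "enzyme_class": key[1],
                "substrate_id": s,
                "confidence": float(rng.uniform(*decoy_confidence)),
            }
        )
    return EsiLibrary(pd.DataFrame(rows, columns=["enzyme_id", "enzyme_class", "substrate_id", "confidence"]))


# Clinical generator defaults: serum glutamine (umol/L) per group, plus
# plausible bone-clinic covariates.  Correlations to Gln are imposed with a
# one-factor Gaussian copula (latent factor = Gln's z-score), which is
# positive-definite for any loadings in (-1, 1).
DEFAULT_PARAMS_NORMAL: dict[str, tuple[float, float]] = {
    "Gln": (534.57, 58.50),
    "BMD": (0.85, 0.10),
    "CTX": (0.35, 0.10),
    "P1NP": (45.0, 12.0),
    "age": (72.0, 5.0),
    "BMI": (23.5, 2.5),
}
DEFAULT_PARAMS_OP: dict[str, tuple[float, float]] = {
    "Gln": (656.87, 58.08),
    "BMD": (0.55, 0.08),
    "CTX": (0.55, 0.15),
    "P1NP": (38.0, 10.0),
    "age": (73.0, 5.0),
    "BMI": (23.0, 2.5),
}
DEFAULT_CORRELATIONS: dict[str, float] = {
    "BMD": -0.79,
    "CTX": 0.6,
    "P1NP": -0.5,
    "age": 0.0,
    "BMI": 0.0,
}


def generate_clinical(
    n_per_group: int = 10,
    params_normal: dict[str, tuple[float, float]] | None = None,
    params_op: dict[str, tuple[float, float]] | None = None,
    correlation_targets: dict[str, float] | None = None,
    seed: int = 0,
) -> ClinicalCohort:
    """Two-group clinical cohort with Gln-anchored correlations.

    Per group, Gln ~ N(mean, sd) with the configured summaries; every other
    variable v satisfies corr(z_v, z_Gln) = correlation_targets[v] within
    group via the one-factor copula.
    """
    params_normal = params_normal or DEFAULT_PARAMS_NORMAL
    params_op = params_op or DEFAULT_PARAMS_OP
    correlation_targets = (
        DEFAULT_CORRELATIONS if correlation_targets is None else correlation_targets
    )
    if set(params_normal) != set(params_op):
        raise ValueError("group parameter dictionaries must share variables")
    bad = {v: r for v, r in correlation_targets.items() if not -1.0 < r < 1.0}
    if bad:
        raise ValueError(f"correlation targets must lie in (-1, 1): {bad}")
    rng = np.random.default_rng(seed)
    variables = list(params_normal)
    rows = []
    for group, params, prefix in (
        ("normal", params_normal, "N"),
        ("OP", params_op, "OP"),
    ):
        f = rng.standard_normal(n_per_group)  # latent factor = Gln z-score
        for i in range(n_per_group):
            row: dict[str, object] = {"subject_id": f"{prefix}{i + 1:02d}", "group": group}
            for v in variables:
                mean, sd = params[v]
                if v == "Gln":
                    z = f[i]
                else:
                    r = float(correlation_targets.get(v, 0.0))
                    z = r * f[i] + np.sqrt(1.0 - r**2) * rng.standard_normal()
                row[v] = mean + sd * z
            rows.append(row)
    df = pd.DataFrame(rows).set_index("subject_id")
    return ClinicalCohort(df, ("normal", "OP"))


def omics_to_tables(
    proteome: AbundanceMatrix,
    ubiquitinome: AbundanceMatrix,
    annotations: list[SiteAnnotation],
    design: SampleDesign,
) -> dict[str, pd.DataFrame]:
    """Simulator outputs as writable input tables (wide dialect)."""
    return {
        "proteome": proteome.values.rename_axis("feature_id").reset_index(),
        "ubiquitinome": ubiquitinome.values.rename_axis("feature_id").reset_index(),
        "annotations": annotations_frame(annotations).rename_axis("site_id").reset_index(),
        "design": pd.DataFrame(
            {
                "sample": list(design.sample_ids),
                "group": [design.group_of[s] for s in design.sample_ids],
            }
        ),
    }
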
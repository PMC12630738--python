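"""Synthetic spatial-transcriptomics cohorts with planted expression programs.

The generator emulates the data regime the discovery pipeline is built
for: a small radical-prostatectomy-style cohort (5 aggressive and 3
non-aggressive patients, 4 samples each — cancer, normal-adjacent and
normal locations), a few hundred Visium-style spots per sample with
histopathology classes drawn from sample-type-specific mixtures, and a
~90% sparse unique-molecule count matrix.

Counts for gene g in spot s are negative binomial with mean
``cells_s * rate_g`` — per-spot cell numbers follow a shifted Poisson
with minimum 1 — plus a Bernoulli dropout whose probability is
calibrated analytically so the realized zero fraction matches the
configured target.  Two programs are planted on top of flat baseline
rates:

* a *global* program (APC-like): genes multiplied (up members) or
  divided (down members) by ``effect_fold`` in every spot of
  aggressive patients;
* a *gland* program (CEG-like): gland-restricted genes, expressed
  mainly in non-cancerous gland (NCG) spots, boosted by
  ``effect_fold`` only in NCG spots of aggressive patients.  These are
  flagged as the "chemokine panel" for the panel-augmentation step.

Per-spot planted activity (the sum of active log-fold multipliers)
drives optional metabolite channels that increase or decrease
monotonically with program activity, mimicking spot-aligned mass
spectrometry imaging intensities on a relative 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotation import AnnotationFractions
from .io import CountMatrix

AGGRESSIVE = "aggressive"
NON_AGGRESSIVE = "non_aggressive"

SAMPLE_TYPES = ("cancer", "normal_adjacent", "normal")


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation configurations."""


#: True-class mixtures per sample type (probabilities must sum to 1).
#: Normal samples carry no cancer classes.  The "excluded" archetype
#: models spots failing the tissue/fold/lumen criteria.
CLASS_MIX: Dict[str, Dict[str, float]] = {
    "cancer": {
        "ISUP1": 0.07, "ISUP2": 0.07, "ISUP3": 0.05, "ISUP4": 0.05,
        "ISUP5": 0.04, "PNI": 0.03, "LYMPHOCYTES": 0.04, "NCG": 0.15,
        "STROMA": 0.30, "LYMPH_ENRICHED_STROMA": 0.12, "excluded": 0.08,
    },
    "normal_adjacent": {
        "ISUP1": 0.03, "ISUP2": 0.02, "ISUP3": 0.01, "ISUP4": 0.01,
        "ISUP5": 0.01, "PNI": 0.01, "LYMPHOCYTES": 0.04, "NCG": 0.22,
        "STROMA": 0.40, "LYMPH_ENRICHED_STROMA": 0.15, "excluded": 0.10,
    },
    "normal": {
        "LYMPHOCYTES": 0.05, "NCG": 0.25, "STROMA": 0.45,
        "LYMPH_ENRICHED_STROMA": 0.15, "excluded": 0.10,
    },
}


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator.

    Defaults reproduce the cohort scale the pipeline targets: 8
    patients (5 aggressive / 3 non-aggressive), 4 samples each (32
    samples: 2 cancer, 1 normal-adjacent, 1 normal), 400 spots per
    sample (~12,800 spots), 1,500 genes, ten-fold planted effects and
    a 90% sparse count matrix.

    Baseline per-cell expression rates are free parameters of the
    simulation.  Background genes draw from a two-component log-normal
    mixture — a small "expressed" fraction with moderate rates and a
    sparse majority — whose defaults put negative-binomial sparsity
    alone at the target zero fraction, so the calibrated dropout is
    near zero under the default configuration.  Planted genes get
    fixed rates high enough to be robustly detected, as the discovery
    rules demand of real signature genes.
    """

    n_aggressive_patients: int = 5
    n_nonaggressive_patients: int = 3
    samples_per_patient: Dict[str, int] = field(
        default_factory=lambda: {"cancer": 2, "normal_adjacent": 1,
                                 "normal": 1}
    )
    spots_per_sample: int = 400
    n_genes: int = 1500
    n_planted_global: int = 20   # split half up / half down
    n_planted_gland: int = 10
    effect_fold: float = 10.0
    mean_cells_per_spot: float = 5.0
    nb_dispersion: float = 2.0
    target_zero_fraction: float = 0.90
    metabolite_channels: Tuple[Tuple[str, str], ...] = (
        ("citrate_like", "decreasing"),
        ("zinc_like", "decreasing"),
        ("choline_like", "increasing"),
    )
    metabolite_noise_sd: float = 0.3
    rng_seed: int = 0

    # baseline rate model (per cell)
    bg_expressed_fraction: float = 0.12
    bg_expressed_rate_median: float = 0.3
    bg_expressed_rate_sigma: float = 1.0
    bg_sparse_rate_median: float = 0.0005
    bg_sparse_rate_sigma: float = 1.5
    planted_up_rate: float = 3.0
    planted_down_rate: float = 30.0
    gland_ncg_rate: float = 3.0
    gland_background_rate: float = 0.002

    # spot geometry (arbitrary units; feeds only the centroid demo)
    grid_spacing: float = 100.0
    spot_radius: float = 27.5

    def __post_init__(self) -> None:
        counts = {
            "n_aggressive_patients": self.n_aggressive_patients,
            "n_nonaggressive_patients": self.n_nonaggressive_patients,
            "spots_per_sample": self.spots_per_sample,
            "n_genes": self.n_genes,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {v}")
        if self.n_planted_global < 0 or self.n_planted_gland < 0:
            raise ConfigurationError("planted gene counts must be >= 0")
        if self.n_planted_global + self.n_planted_gland > self.n_genes:
            raise ConfigurationError("more planted genes than genes")
        if self.effect_fold < 1:
            raise ConfigurationError("effect_fold must be >= 1")
        if not (0 <= self.target_zero_fraction < 1):
            raise ConfigurationError("target_zero_fraction must be in [0, 1)")
        if self.mean_cells_per_spot <= 0 or self.nb_dispersion <= 0:
            raise ConfigurationError(
                "mean_cells_per_spot and nb_dispersion must be positive"
            )
        for _, direction in self.metabolite_channels:
            if direction not in ("increasing", "decreasing"):
                raise ConfigurationError(
                    f"unknown metabolite direction {direction!r}"
                )
        unknown = set(self.samples_per_patient) - set(SAMPLE_TYPES)
        if unknown:
            raise ConfigurationError(f"unknown sample types {unknown}")
        if sum(self.samples_per_patient.values()) < 1:
            raise ConfigurationError("each patient needs at least one sample")

    @property
    def n_patients(self) -> int:
        return self.n_aggressive_patients + self.n_nonaggressive_patients

    @property
    def n_samples(self) -> int:
        return self.n_patients * sum(self.samples_per_patient.values())


@dataclass
class GroundTruth:
    """Planted-program labels and activity for recovery tests."""

    gene_labels: pd.Series       # gene -> {global-up, global-down, gland-up, none}
    spot_activity: pd.Series     # barcode -> planted activity (log10 fold sum)
    true_class: pd.Series        # barcode -> true class string

    @property
    def planted_global_up(self) -> List[str]:
        return list(self.gene_labels.index[self.gene_labels == "global-up"])

    @property
    def planted_global_down(self) -> List[str]:
        return list(self.gene_labels.index[self.gene_labels == "global-down"])

    @property
    def planted_gland(self) -> List[str]:
        return list(self.gene_labels.index[self.gene_labels == "gland-up"])


# ---------------------------------------------------------------------------
# annotation fractions

def generate_annotation_fractions(
    true_class: str, rng: np.random.Generator
) -> AnnotationFractions:
    """Draw annotation-area fractions consistent with a true class.

    The dominant fraction clears its classification threshold with
    margin, so the rule-based classifier recovers the true class for
    essentially all draws; remaining area is spread below the
    competing thresholds.  ``true_class='excluded'`` draws one of the
    exclusion archetypes (low tissue, folded tissue, dominant lumen,
    or no criterion met).
    """
    f = dict(tissue=float(rng.uniform(0.85, 1.0)),
             folded_or_lowquality=float(rng.uniform(0.0, 0.10)))

    def spread(remaining: float) -> Dict[str, float]:
        # background areas below every threshold
        out = {}
        out["lumen"] = min(remaining, float(rng.uniform(0.0, 0.25)))
        remaining -= out["lumen"]
        out["stroma"] = min(remaining, float(rng.uniform(0.0, 0.25)))
        remaining -= out["stroma"]
        out["non_cancer_glands"] = min(remaining,
                                       float(rng.uniform(0.0, 0.20)))
        return out

    if true_class == "excluded":
        archetype = rng.choice(
            ["low_tissue", "folded", "lumen", "no_criterion"]
        )
        if archetype == "low_tissue":
            f["tissue"] = float(rng.uniform(0.0, 0.45))
        elif archetype == "folded":
            f["folded_or_lowquality"] = float(rng.uniform(0.55, 0.95))
        elif archetype == "lumen":
            f["lumen"] = float(rng.uniform(0.85, 1.0))
        else:
            # tissue fine, but every sub-fraction below its threshold
            f.update(stroma=float(rng.uniform(0.0, 0.25)),
                     lymphocyte_enriched_stroma=float(rng.uniform(0.0, 0.20)),
                     non_cancer_glands=float(rng.uniform(0.0, 0.25)),
                     lumen=float(rng.uniform(0.0, 0.25)))
        return AnnotationFractions(**f)

    if true_class in ("STROMA", "LYMPH_ENRICHED_STROMA"):
        total = float(rng.uniform(0.60, 0.95))
        major = float(rng.uniform(0.60, 0.95)) * total
        minor = total - major
        if true_class == "STROMA":
            f["stroma"], f["lymphocyte_enriched_stroma"] = major, minor
        else:
            f["lymphocyte_enriched_stroma"], f["stroma"] = major, minor
        f["lumen"] = min(1.0 - total, float(rng.uniform(0.0, 0.2)))
        return AnnotationFractions(**f)

    if true_class == "NCG":
        ncg = float(rng.uniform(0.35, 0.85))
        rest = spread(1.0 - ncg)
        rest["stroma"] = min(rest["stroma"], 0.25)
        rest.pop("non_cancer_glands", None)
        f.update(rest)
        f["non_cancer_glands"] = ncg
        return AnnotationFractions(**f)

    field_map = {
        "ISUP1": "isup1", "ISUP2": "isup2", "ISUP3": "isup3",
        "ISUP4": "isup4", "ISUP5": "isup5", "ISUPX": "isupx",
        "ISUPY": "isupy", "PNI": "pni", "LYMPHOCYTES": "lymphocytes",
    }
    if true_class not in field_map:
        raise ConfigurationError(f"unsupported true class {true_class!r}")
    main = float(rng.uniform(0.55, 0.90))
    f[field_map[true_class]] = main
    rest = spread(1.0 - main)
    f.update(rest)
    return AnnotationFractions(**f)


# ---------------------------------------------------------------------------
# cohort generation

def _nb_zero_fraction(mu: np.ndarray, r: float) -> float:
    """Expected zero fraction of NB(mean=mu, dispersion=r) entries."""
    return float(np.mean((1.0 + mu / r) ** (-r)))


def generate_metabolites(
    spot_activity: pd.Series,
    channels: Sequence[Tuple[str, str]],
    rng: np.random.Generator,
    noise_sd: float = 0.3,
) -> pd.DataFrame:
    """Per-spot metabolite intensities monotonically coupled to activity.

    A "decreasing" channel falls with planted activity (citrate/zinc
    pattern: highest in low-activity spots), an "increasing" channel
    rises.  Gaussian noise with standard deviation ``noise_sd`` times
    the activity range is added before min-max scaling to a relative
    0-100 intensity.  With zero noise and non-constant activity the
    Spearman correlation with activity is exactly +/-1.
    """
    act = spot_activity.to_numpy(dtype=float)
    span = act.max() - act.min()
    scale = span if span > 0 else 1.0
    out = {}
    for name, direction in channels:
        if direction == "decreasing":
            base = -act
        elif direction == "increasing":
            base = act.copy()
        else:
            raise ConfigurationError(
                f"unknown metabolite direction {direction!r}"
            )
        vals = base + rng.normal(0.0, noise_sd * scale, size=act.size)
        lo, hi = vals.min(), vals.max()
        out[name] = np.zeros(act.size) if hi == lo else \
            np.clip(100.0 * (vals - lo) / (hi - lo), 0.0, 100.0)
    return pd.DataFrame(out, index=spot_activity.index)


def generate_cohort(config: Optional[SimulationConfig] = None):
    """Generate one synthetic cohort.

    Returns ``(spots, counts, truth, metabolites, bulk)``:

    * ``spots`` — per-spot metadata table (barcode index; sample,
      patient, status, sample type, grid coordinates, cell count,
      annotation fractions, true class);
    * ``counts`` — :class:`~spotsig.io.CountMatrix` of sparse genes x
      spots raw counts, gene order matching ``bulk``;
    * ``truth`` — :class:`GroundTruth`;
    * ``metabolites`` — spot x channel relative intensities;
    * ``bulk`` — genes x samples raw counts, the exact per-sample sum
      of spot counts.

    Deterministic for a fixed config (including seed).
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.rng_seed)

    genes = [f"GENE{i:05d}" for i in range(cfg.n_genes)]
    planted_idx = rng.choice(
        cfg.n_genes, size=cfg.n_planted_global + cfg.n_planted_gland,
        replace=False,
    )
    n_up = cfg.n_planted_global // 2 + cfg.n_planted_global % 2
    up_idx = planted_idx[:n_up]
    down_idx = planted_idx[n_up:cfg.n_planted_global]
    gland_idx = planted_idx[cfg.n_planted_global:]

    labels = pd.Series("none", index=pd.Index(genes, name="gene"))
    labels.iloc[up_idx] = "global-up"
    labels.iloc[down_idx] = "global-down"
    labels.iloc[gland_idx] = "gland-up"

    # baseline per-cell rates: expressed / sparse mixture
    expressed = rng.random(cfg.n_genes) < cfg.bg_expressed_fraction
    rates = np.where(
        expressed,
        rng.lognormal(np.log(cfg.bg_expressed_rate_median),
                      cfg.bg_expressed_rate_sigma, size=cfg.n_genes),
        rng.lognormal(np.log(cfg.bg_sparse_rate_median),
                      cfg.bg_sparse_rate_sigma, size=cfg.n_genes),
    )
    rates[up_idx] = cfg.planted_up_rate
    rates[down_idx] = cfg.planted_down_rate
    rates[gland_idx] = cfg.gland_background_rate

    # spot metadata
    rows = []
    frac_rows = []
    patients = (
        [(f"P{i+1:02d}", AGGRESSIVE)
         for i in range(cfg.n_aggressive_patients)]
        + [(f"P{i+1+cfg.n_aggressive_patients:02d}", NON_AGGRESSIVE)
           for i in range(cfg.n_nonaggressive_patients)]
    )
    side = int(np.ceil(np.sqrt(cfg.spots_per_sample)))
    sample_counter = 0
    for patient, status in patients:
        for stype in SAMPLE_TYPES:
            for rep in range(cfg.samples_per_patient.get(stype, 0)):
                sample_counter += 1
                sample = f"S{sample_counter:03d}"
                mix = CLASS_MIX[stype]
                names = list(mix)
                probs = np.asarray([mix[c] for c in names])
                probs = probs / probs.sum()
                drawn = rng.choice(len(names), size=cfg.spots_per_sample,
                                   p=probs)
                cells = 1 + rng.poisson(
                    max(cfg.mean_cells_per_spot - 1.0, 0.0),
                    size=cfg.spots_per_sample,
                )
                for k in range(cfg.spots_per_sample):
                    cls = names[drawn[k]]
                    barcode = f"{sample}_spot{k:04d}"
                    x = (k % side) * cfg.grid_spacing
                    y = (k // side) * cfg.grid_spacing
                    rows.append((barcode, sample, patient, status, stype,
                                 x, y, int(cells[k]), cls))
                    frac_rows.append(
                        generate_annotation_fractions(cls, rng)
                    )
    spots = pd.DataFrame(
        rows,
        columns=["barcode", "sample_id", "patient_id", "status",
                 "sample_type", "x", "y", "cell_count", "true_class"],
    ).set_index("barcode")
    frac_cols = [
        "tissue", "folded_or_lowquality", "lumen", "stroma",
        "lymphocyte_enriched_stroma", "isup1", "isup2", "isup3", "isup4",
        "isup5", "isupx", "isupy", "pni", "lymphocytes",
        "non_cancer_glands",
    ]
    fracs = pd.DataFrame(
        [[getattr(f, c) for c in frac_cols] for f in frac_rows],
        columns=frac_cols, index=spots.index,
    )
    spots = pd.concat([spots, fracs], axis=1)

    # mean matrix: genes x spots
    n_spots = len(spots)
    cells = spots["cell_count"].to_numpy(dtype=float)
    is_agg = (spots["status"] == AGGRESSIVE).to_numpy()
    is_ncg = (spots["true_class"] == "NCG").to_numpy()

    mu = np.outer(rates, cells).astype(np.float64)
    if cfg.n_planted_global:
        mu[up_idx[:, None], np.flatnonzero(is_agg)] *= cfg.effect_fold
        mu[down_idx[:, None], np.flatnonzero(is_agg)] /= cfg.effect_fold
    if cfg.n_planted_gland:
        # gland program lives in NCG spots of everyone, boosted when
        # the patient is aggressive
        ncg_cols = np.flatnonzero(is_ncg)
        mu[gland_idx[:, None], ncg_cols] = np.outer(
            np.full(gland_idx.size, cfg.gland_ncg_rate), cells[ncg_cols]
        )
        agg_ncg = np.flatnonzero(is_ncg & is_agg)
        mu[gland_idx[:, None], agg_ncg] *= cfg.effect_fold

    r = cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)

    # dropout calibrated to the target zero fraction
    zf_nb = _nb_zero_fraction(mu, r)
    p_drop = 0.0
    if zf_nb < cfg.target_zero_fraction:
        p_drop = (cfg.target_zero_fraction - zf_nb) / (1.0 - zf_nb)
        keep = rng.random(counts.shape) >= p_drop
        counts *= keep

    # planted activity (log10 fold multipliers active per spot)
    log_fold = float(np.log10(cfg.effect_fold))
    activity = np.zeros(n_spots)
    if cfg.n_planted_global:
        activity += log_fold * is_agg
    if cfg.n_planted_gland:
        activity += log_fold * (is_agg & is_ncg)
    truth = GroundTruth(
        gene_labels=labels,
        spot_activity=pd.Series(activity, index=spots.index,
                                name="activity"),
        true_class=spots["true_class"].copy(),
    )

    metabolites = generate_metabolites(
        truth.spot_activity, cfg.metabolite_channels, rng,
        noise_sd=cfg.metabolite_noise_sd,
    )

    sample_ids = spots["sample_id"].to_numpy()
    bulk = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for sample in pd.unique(sample_ids):
        bulk[sample] = counts[:, sample_ids == sample].sum(axis=1)

    cm = CountMatrix(sp.csr_matrix(counts), genes, list(spots.index))
    return spots, cm, truth, metabolites, bulk
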
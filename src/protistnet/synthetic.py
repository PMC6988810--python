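"""Synthetic two-habitat metabarcoding OTU tables with planted ground truth.

The generator emulates the statistical structure of a processed 18S-V4 OTU
table from a paired lagoon/sea sampling design: a fixed station layout
sampled on several dates in duplicate, lognormally dominated OTU mean
abundances with a long rare tail, unequal per-sample library sizes
(motivating rarefaction), habitat specialists whose expected abundance is a
fold-change higher in their preferred habitat, seasonal turnover, and
optional blocks of co-occurring OTUs driven by shared latent factors (the
signal the MIC network stage should recover). Per-sample counts are
multinomial draws from the per-sample expected relative abundances, so
column sums equal the drawn library sizes exactly.

Every OTU's planted habitat class, taxonomic group, trophic class and
association-block membership is returned as a ``SyntheticTruth`` for
recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .otu import OtuTable

# Taxonomic groups used for synthetic lineages, with a PR2-like 8-rank
# lineage skeleton and the trophic class the default rules imply.
_GROUPS = [
    ("Bacillariophyta", "Eukaryota;Stramenopiles;Ochrophyta;Bacillariophyta", "autotroph"),
    ("Mamiellophyceae", "Eukaryota;Archaeplastida;Chlorophyta;Mamiellophyceae", "autotroph"),
    ("Dinophyceae", "Eukaryota;Alveolata;Dinoflagellata;Dinophyceae", "mixotroph"),
    ("Cryptophyceae", "Eukaryota;Hacrobia;Cryptophyta;Cryptophyceae", "mixotroph"),
    ("Chrysophyceae", "Eukaryota;Stramenopiles;Ochrophyta;Chrysophyceae", "mixotroph"),
    ("Ciliophora", "Eukaryota;Alveolata;Ciliophora;Spirotrichea", "heterotroph"),
    ("MAST", "Eukaryota;Stramenopiles;Opalozoa;MAST", "heterotroph"),
    ("Cercozoa", "Eukaryota;Rhizaria;Cercozoa;Filosa", "heterotroph"),
    ("Syndiniales", "Eukaryota;Alveolata;Dinoflagellata;Syndiniales", "parasite"),
    ("Labyrinthulea", "Eukaryota;Stramenopiles;Sagenista;Labyrinthulea", "parasite"),
    ("Dinophyceae_XXX", "Eukaryota;Alveolata;Dinoflagellata;Dinophyceae_XXX", "NA"),
]

GENERALIST = "generalist"
SPECIALIST_A = "specialist_A"
SPECIALIST_B = "specialist_B"
RARE = "rare"


@dataclass(frozen=True)
class AssociationBlock:
    """A planted group of co-occurring OTUs.

    habitat : 'A', 'B' or 'both' — the block members are planted as
        specialists of that habitat (or generalists for 'both').
    size : number of member OTUs.
    strength : standard deviation of the shared latent log-normal factor;
        larger values induce stronger positive rank association.
    """

    habitat: str
    size: int
    strength: float = 1.5


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design and effect sizes for the generator.

    Defaults mirror a lagoon/sea paired design: 4 + 3 stations sampled on 4
    dates in duplicate (56 samples), a lognormal abundance distribution
    dominated by few OTUs, an 8-fold habitat preference for specialists and
    a 4-fold seasonal preference.
    """

    n_otus: int = 1200
    n_stations_a: int = 4
    n_stations_b: int = 3
    n_dates: int = 4
    n_replicates: int = 2
    depth_mean: float = 20000.0
    depth_dispersion: float = 0.3
    base_abundance_sigma: float = 1.8
    habitat_effect: float = 8.0
    frac_specialist_a: float = 0.15
    frac_specialist_b: float = 0.15
    frac_generalist: float = 0.20
    season_effect: float = 4.0
    rare_scale: float = 0.002
    # per-OTU per-sample lognormal overdispersion (0 = pure multinomial
    # sampling around the expected composition)
    otu_noise_sigma: float = 0.0
    association_blocks: tuple[AssociationBlock, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.frac_specialist_a, self.frac_specialist_b, self.frac_generalist)
        if any(f < 0 or f > 1 for f in fr) or sum(fr) > 1:
            raise ValueError(f"class fractions must lie in [0,1] and sum <= 1, got {fr}")
        if self.habitat_effect < 1 or self.season_effect < 1:
            raise ValueError("habitat_effect and season_effect must be >= 1")
        if min(self.n_otus, self.n_stations_a, self.n_stations_b,
               self.n_dates, self.n_replicates) < 1:
            raise ValueError("design dimensions must be positive")
        needed = sum(b.size for b in self.association_blocks)
        if needed > self.n_otus * sum(fr):
            raise ValueError("association blocks need more OTUs than the "
                             "non-rare fractions provide")

    @property
    def n_samples(self) -> int:
        return (self.n_stations_a + self.n_stations_b) * self.n_dates * self.n_replicates


@dataclass
class SyntheticTruth:
    """Planted per-OTU ground truth."""

    habitat_class: dict[str, str]
    group: dict[str, str]
    trophic_class: dict[str, str]
    block: dict[str, int | None] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "habitat_class": pd.Series(self.habitat_class),
                "group": pd.Series(self.group),
                "trophic_class": pd.Series(self.trophic_class),
                "block": pd.Series(
                    {k: (-1 if v is None else v) for k, v in self.block.items()}
                ),
            }
        ).rename_axis("otu_id")


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[OtuTable, pd.DataFrame, dict[str, str], SyntheticTruth]:
    """Draw one synthetic dataset.

    Returns (table, metadata, taxonomy, truth). Reproducible for a fixed
    ``cfg.seed``; column sums equal the drawn library sizes exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_otus
    otu_ids = [f"OTU{i:05d}" for i in range(n)]

    # --- planted classes ---------------------------------------------------
    n_a = int(round(cfg.frac_specialist_a * n))
    n_b = int(round(cfg.frac_specialist_b * n))
    n_g = int(round(cfg.frac_generalist * n))
    classes = np.array(
        [SPECIALIST_A] * n_a + [SPECIALIST_B] * n_b + [GENERALIST] * n_g
        + [RARE] * (n - n_a - n_b - n_g),
        dtype=object,
    )

    # --- association blocks take members from matching classes -------------
    block_of = np.full(n, -1, dtype=np.int64)
    pools = {
        "A": [i for i in range(n) if classes[i] == SPECIALIST_A],
        "B": [i for i in range(n) if classes[i] == SPECIALIST_B],
        "both": [i for i in range(n) if classes[i] == GENERALIST],
    }
    for b_id, block in enumerate(cfg.association_blocks):
        pool = pools[block.habitat]
        if len(pool) < block.size:
            raise ValueError(
                f"block {b_id} ({block.habitat}) needs {block.size} OTUs, "
                f"only {len(pool)} available"
            )
        members, pools[block.habitat] = pool[: block.size], pool[block.size:]
        block_of[members] = b_id

    # --- abundance model ----------------------------------------------------
    base = rng.lognormal(mean=0.0, sigma=cfg.base_abundance_sigma, size=n)
    base[classes == RARE] *= cfg.rare_scale
    preferred_date = rng.integers(0, cfg.n_dates, size=n)

    # --- design -------------------------------------------------------------
    stations = [f"StA{i + 1}" for i in range(cfg.n_stations_a)] + [
        f"StB{i + 1}" for i in range(cfg.n_stations_b)
    ]
    habitats = ["A"] * cfg.n_stations_a + ["B"] * cfg.n_stations_b
    dates = [f"M{d + 1}" for d in range(cfg.n_dates)]

    meta_rows = []
    cols: dict[str, np.ndarray] = {}
    hab_mult = np.ones((n, 2))  # columns: habitat A, habitat B
    hab_mult[classes == SPECIALIST_A, 0] = cfg.habitat_effect
    hab_mult[classes == SPECIALIST_B, 1] = cfg.habitat_effect

    for d_idx, date in enumerate(dates):
        season = np.where(preferred_date == d_idx, cfg.season_effect, 1.0)
        # per-(block, date-station-replicate) latent factors drawn per sample
        for s_idx, (station, hab) in enumerate(zip(stations, habitats)):
            for rep in range(1, cfg.n_replicates + 1):
                sample_id = f"{station}_{date}_r{rep}"
                lam = base * season * hab_mult[:, 0 if hab == "A" else 1]
                for b_id, block in enumerate(cfg.association_blocks):
                    factor = rng.lognormal(0.0, block.strength)
                    lam = np.where(block_of == b_id, lam * factor, lam)
                if cfg.otu_noise_sigma > 0:
                    lam = lam * rng.lognormal(0.0, cfg.otu_noise_sigma, size=n)
                p = lam / lam.sum()
                depth = max(
                    int(round(rng.lognormal(np.log(cfg.depth_mean),
                                            cfg.depth_dispersion))),
                    1,
                )
                cols[sample_id] = rng.multinomial(depth, p)
                meta_rows.append(
                    {"sample_id": sample_id, "station": station, "habitat": hab,
                     "date": date, "replicate": str(rep)}
                )

    counts = pd.DataFrame(cols, index=pd.Index(otu_ids, name="otu_id"))
    metadata = pd.DataFrame(meta_rows)

    # --- taxonomy and trophic truth ----------------------------------------
    grp_idx = rng.integers(0, len(_GROUPS), size=n)
    taxonomy, group, trophic = {}, {}, {}
    for i, otu in enumerate(otu_ids):
        g_name, g_lineage, g_trophic = _GROUPS[grp_idx[i]]
        taxonomy[otu] = f"{g_lineage};{g_name}_sp{i % 7 + 1}"
        group[otu] = g_name
        trophic[otu] = g_trophic

    truth = SyntheticTruth(
        habitat_class={otu_ids[i]: str(classes[i]) for i in range(n)},
        group=group,
        trophic_class=trophic,
        block={otu_ids[i]: (None if block_of[i] < 0 else int(block_of[i]))
               for i in range(n)},
    )
    return OtuTable(counts=counts, taxonomy=taxonomy), metadata, taxonomy, truth


def truth_confusion(truth: SyntheticTruth, clam_results) -> pd.DataFrame:
    """Cross-tabulate planted habitat classes against CLAM calls.

    Returns the confusion table with per-class recall appended as a column;
    the false-specialist rate among planted generalists is available as
    ``frame.attrs['false_specialist_rate_generalists']``.
    """
    planted = pd.Series(truth.habitat_class, name="planted")
    called = clam_results.classes
    shared = planted.index.intersection(called.index)
    if len(shared) == 0:
        raise ValueError("truth and CLAM result share no OTU ids")
    planted = planted.loc[shared]
    called = called.loc[shared].rename("called")
    tab = pd.crosstab(planted, called)
    # ensure all four call columns exist
    for c in ("generalist", "specialist_A", "specialist_B", "too_rare"):
        if c not in tab.columns:
            tab[c] = 0
    tab = tab[["generalist", "specialist_A", "specialist_B", "too_rare"]]
    recall = {}
    for cls in tab.index:
        target = cls if cls != RARE else "too_rare"
        total = tab.loc[cls].sum()
        recall[cls] = float(tab.loc[cls, target] / total) if total else np.nan
    tab["recall"] = pd.Series(recall)
    gen = planted.index[planted == GENERALIST]
    if len(gen):
        false_spec = called.loc[gen].isin(["specialist_A", "specialist_B"]).mean()
    else:
        false_spec = np.nan
    tab.attrs["false_specialist_rate_generalists"] = float(false_spec)
    return tab
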
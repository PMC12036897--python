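"""Synthetic F2 crosses with viability selection.

Each individual draws an independent Mendelian genotype (1/4, 1/2, 1/4) at
every segregating locus; non-segregating loci are fixed RR.  Survival to
observation is the product of all applicable survival rates — per-genotype
rates at single loci and per-genotype-combination rates at locus pairs —
and survivors are accumulated by rejection sampling until the target cohort
size is reached.  This is the zygotic (post-fertilisation) selection model:
distortion and co-occurrence arise only through differential survival,
never through transmission bias, and loci are unlinked.  The generator
returns the planted effects alongside the matrix so tests can check
recovery against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GENOTYPES, GenotypeMatrix

_STUDY_CROSS_SIZES = {
    "62": 92, "155": 188, "444": 148, "502": 163, "541": 164,
    "664": 157, "909": 148, "1034": 151, "1192": 162,
}


@dataclass
class CrossConfig:
    """Ground-truth description of one simulated cross."""

    cross_id: str
    n_individuals: int
    loci: list[tuple[str, str, bool]]  # (locus_id, chromosome, segregating)
    single_locus_survival: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    pair_survival: dict[tuple[str, str], tuple] = field(default_factory=dict)
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        chrom = {l: c for l, c, _ in self.loci}
        known = set(chrom)
        for locus, s in self.single_locus_survival.items():
            s = np.asarray(s, dtype=float)
            if locus not in known:
                raise ValueError(f"survival effect on unknown locus {locus!r}")
            if s.shape != (3,) or (s < 0).any() or (s > 1).any() or not (s > 0).any():
                raise ValueError(f"invalid survival rates for {locus!r}")
        for (a, b), s in self.pair_survival.items():
            s = np.asarray(s, dtype=float)
            if a not in known or b not in known:
                raise ValueError(f"pair effect on unknown loci ({a!r}, {b!r})")
            if chrom[a] == chrom[b]:
                raise ValueError("pair effects allowed only between chromosomes")
            if s.shape != (9,) or (s < 0).any() or (s > 1).any() or not (s > 0).any():
                raise ValueError(f"invalid pair survival rates for ({a!r}, {b!r})")


def simulate_f2_cross(cfg: CrossConfig) -> tuple[GenotypeMatrix, dict]:
    """Simulate one F2 cross; returns (matrix, ground-truth registry)."""
    rng = np.random.default_rng(cfg.seed)
    seg = [l for l, _, s in cfg.loci if s]
    fixed = [l for l, _, s in cfg.loci if not s]
    idx = {l: k for k, l in enumerate(seg)}

    # quick impossibility check: any effect with all-zero joint survival
    for locus, s in cfg.single_locus_survival.items():
        if locus in idx and not np.any(np.asarray(s) > 0):
            raise ValueError("all-zero joint survival")

    survivors: list[np.ndarray] = []
    need = cfg.n_individuals
    attempts = 0
    while need > 0:
        batch = max(4 * need, 200)
        geno = rng.choice(3, size=(batch, len(seg)), p=[0.25, 0.5, 0.25])
        w = np.ones(batch)
        for locus, s in cfg.single_locus_survival.items():
            if locus in idx:
                w *= np.asarray(s, dtype=float)[geno[:, idx[locus]]]
        for (a, b), s in cfg.pair_survival.items():
            if a in idx and b in idx:
                cell = 3 * geno[:, idx[a]] + geno[:, idx[b]]
                w *= np.asarray(s, dtype=float)[cell]
        keep = rng.random(batch) < w
        survivors.append(geno[keep])
        need -= int(keep.sum())
        attempts += 1
        if attempts > 200 and not any(len(s) for s in survivors):
            raise ValueError("all-zero joint survival: no individual can survive")
    geno = np.concatenate(survivors)[: cfg.n_individuals]

    codes = np.array(GENOTYPES, dtype=object)
    data = pd.DataFrame(
        codes[geno],
        index=[f"{cfg.cross_id}_{i + 1}" for i in range(cfg.n_individuals)],
        columns=seg,
        dtype=object,
    )
    for l in fixed:
        data[l] = "RR"
    data = data[[l for l, _, _ in cfg.loci]]  # original locus order
    if cfg.missing_rate > 0:
        mask = rng.random(data.shape) < cfg.missing_rate
        arr = data.to_numpy(dtype=object)
        arr[mask] = np.nan
        data = pd.DataFrame(arr, index=data.index, columns=data.columns)

    truth = {
        "cross_id": cfg.cross_id,
        "segregating": seg,
        "single_locus_survival": {l: list(map(float, s)) for l, s in cfg.single_locus_survival.items()},
        "pair_survival": {f"{a}|{b}": list(map(float, s)) for (a, b), s in cfg.pair_survival.items()},
        "missing_rate": cfg.missing_rate,
        "seed": cfg.seed,
    }
    return GenotypeMatrix(data, cross_id=cfg.cross_id), truth


def default_locus_panel(n_loci: int = 64, n_chromosomes: int = 14) -> pd.Series:
    """Locus → chromosome map for the default panel (round-robin layout)."""
    loci = [f"Inv_{i + 1}" for i in range(n_loci)]
    return pd.Series(
        [f"chr{(i % n_chromosomes) + 1}" for i in range(n_loci)], index=loci,
        name="chromosome",
    )


def default_nine_cross_configs(
    seed: int = 0,
    plant_effects: bool = True,
    seg_prob: float = 0.68,
    missing_rate: float = 0.02,
) -> tuple[list[CrossConfig], pd.Series]:
    """Nine-cross study design emulating the real F2 panel.

    Cross sizes match the surviving-cohort sizes of the nine crosses
    (92–188 plants); 64 loci spread over 14 chromosomes; loci Inv_29,
    Inv_32 and Inv_40 segregate in every cross while the rest segregate
    per-cross with probability ``seg_prob`` (≈46% of locus pairs valid).
    When ``plant_effects`` is set, one recessive-lethal locus (Inv_49 in
    cross 444, s_II = 0) and two pairwise incompatibilities (survival 0.2
    for the double inverted homozygote) are planted.

    Returns (configs, locus metadata).
    """
    meta = default_locus_panel()
    rng = np.random.default_rng(seed)
    always = {"Inv_29", "Inv_32", "Inv_40"}
    configs = []
    for k, (cross, n) in enumerate(_STUDY_CROSS_SIZES.items()):
        seg_mask = {
            l: (l in always) or (rng.random() < seg_prob) for l in meta.index
        }
        single: dict[str, tuple[float, float, float]] = {}
        pairs: dict[tuple[str, str], tuple] = {}
        if plant_effects:
            s = [1.0] * 9
            s[8] = 0.2  # (II, II) incompatibility
            if cross == "444":
                seg_mask["Inv_49"] = True
                single["Inv_49"] = (1.0, 1.0, 0.0)  # recessive lethal
            elif cross == "155":
                seg_mask["Inv_35"] = seg_mask["Inv_43"] = True
                pairs[("Inv_35", "Inv_43")] = tuple(s)
            elif cross == "502":
                seg_mask["Inv_27"] = seg_mask["Inv_31"] = True
                pairs[("Inv_27", "Inv_31")] = tuple(s)
        loci = [(l, meta[l], seg_mask[l]) for l in meta.index]
        configs.append(
            CrossConfig(
                cross_id=cross,
                n_individuals=n,
                loci=loci,
                single_locus_survival=single,
                pair_survival=pairs,
                missing_rate=missing_rate,
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    return configs, meta


def simulate_study(
    seed: int = 0, plant_effects: bool = True
) -> tuple[dict[str, GenotypeMatrix], pd.Series, dict]:
    """Simulate the full nine-cross study; returns (crosses, meta, truth)."""
    configs, meta = default_nine_cross_configs(seed=seed, plant_effects=plant_effects)
    crosses: dict[str, GenotypeMatrix] = {}
    truth: dict = {}
    for cfg in configs:
        m, t = simulate_f2_cross(cfg)
        crosses[cfg.cross_id] = m
        truth[cfg.cross_id] = t
    return crosses, meta, truth
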
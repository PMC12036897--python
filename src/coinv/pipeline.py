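"""End-to-end orchestration of the per-cross analysis.

Stage order mirrors the study workflow: per-cross segregation-distortion
table (BH within cross) → valid-pair enumeration → omnibus + post-hoc
contingency tests → four-way co-occurrence contrasts → network + motif
statistics → replicated G for dosage states of loci shared by all crosses
→ SDV-vs-interaction summary.  Every stage writes a plain-text artifact
and the run log records seeds and valid/skipped-contrast counts so the
pair accounting is auditable.  Outputs are a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cooccurrence import contrasts_frame, pairwise_contrasts
from .io import HET, HOM_INV, DosageState, GenotypeMatrix, enumerate_valid_pairs
from .network import (
    build_network,
    motif_enrichment,
    replicated_g_from_crosses,
    sdv_interaction_summary,
    significant_subgraph,
)
from .segdist import sd_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    expectation: str = "margins"
    B: int = 10_000
    alpha_cap: float = 10.0
    level: float = 0.05
    motif_R: int = 1000
    swaps_per_edge: int = 10
    min_count: int = 200
    seed: int = 0
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.B < 1 or self.motif_R < 1 or self.swaps_per_edge < 1:
            raise ValueError("replicate counts must be >= 1")
        if not (0.0 < self.level < 1.0):
            raise ValueError("significance level must be in (0, 1)")


def _write(df: pd.DataFrame, out_dir: Path | None, name: str) -> None:
    if out_dir is not None:
        df.to_csv(out_dir / name, sep="\t", index=False, float_format="%.6g")


def run_pipeline(
    crosses: dict[str, GenotypeMatrix],
    meta: pd.Series,
    cfg: RunConfig | None = None,
) -> dict:
    """Run the full workflow over a set of crosses.

    Returns a dict of result tables; writes TSV/GraphML/JSON artifacts to
    ``cfg.out_dir`` when set.
    """
    cfg = cfg or RunConfig()
    out_dir = Path(cfg.out_dir) if cfg.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(cfg.seed)
    log: dict = {"seed": cfg.seed, "crosses": {}}

    sd_frames, omnibus_rows, contrast_results = [], [], []
    networks: dict[str, nx.Graph] = {}
    motif_frames = []

    for cross_id, m in sorted(crosses.items()):
        rng = np.random.default_rng(master.integers(2**31 - 1))
        sd = sd_table(m)
        sd_frames.append(sd)
        _write(sd, out_dir, f"sd_{cross_id}.tsv")

        locus_pairs = enumerate_valid_pairs(m, meta, level="locus")
        state_pairs = enumerate_valid_pairs(m, meta, level="state")
        results = []
        skipped = 0
        for a, b in locus_pairs:
            pr = pairwise_contrasts(
                m, a, b, meta=meta, B=cfg.B, rng=rng,
                expectation=cfg.expectation, cap=cfg.alpha_cap, level=cfg.level,
            )
            skipped += len(pr.skipped)
            results.append(pr)
            omnibus_rows.append(
                {"cross": cross_id, "locus_a": a, "locus_b": b,
                 "chi2": pr.omnibus.stat, "p": pr.omnibus.p, "n": pr.n}
            )
        contrast_results.extend(results)
        log["crosses"][cross_id] = {
            "n_individuals": m.n_individuals,
            "valid_locus_pairs": len(locus_pairs),
            "valid_state_pairs": len(state_pairs),
            "skipped_contrasts": skipped,
        }

        flat = [c for pr in results for c in pr.contrasts]
        g = build_network(flat, alpha_level=cfg.level, meta=meta)
        networks[cross_id] = g
        if out_dir is not None and g.number_of_nodes():
            nx.write_graphml(g, out_dir / f"network_{cross_id}.graphml")
            edges = nx.to_pandas_edgelist(g)
            _write(edges, out_dir, f"edges_{cross_id}.tsv")
        sig = significant_subgraph(g)
        if sig.number_of_edges() >= 2:
            mo = motif_enrichment(
                sig, R=cfg.motif_R, swaps_per_edge=cfg.swaps_per_edge,
                min_count=cfg.min_count, seed=int(rng.integers(2**31 - 1)),
            )
            mo.insert(0, "cross", cross_id)
            motif_frames.append(mo)

    omnibus = pd.DataFrame(omnibus_rows)
    if not omnibus.empty:
        # BH within cross, matching the per-line correction policy
        omnibus["p_adj"] = np.nan
        for cross_id, grp in omnibus.groupby("cross"):
            omnibus.loc[grp.index, "p_adj"] = multipletests(grp["p"].values, method="fdr_bh")[1]
    _write(omnibus, out_dir, "omnibus.tsv")

    contrasts = contrasts_frame(contrast_results)
    _write(contrasts, out_dir, "contrasts.tsv")

    motifs = pd.concat(motif_frames, ignore_index=True) if motif_frames else pd.DataFrame()
    _write(motifs, out_dir, "motifs.tsv")

    # replicated G over dosage states of loci segregating in every cross
    shared = set(meta.index)
    from .io import segregating_loci

    for m in crosses.values():
        shared &= set(segregating_loci(m))
    rep_rows = []
    shared = sorted(shared)
    for i, la in enumerate(shared):
        for lb in shared[i + 1:]:
            if meta[la] == meta[lb]:
                continue
            for sa in (HET, HOM_INV):
                for sb in (HET, HOM_INV):
                    da, db = DosageState(la, sa), DosageState(lb, sb)
                    rg = replicated_g_from_crosses(crosses, da, db)
                    rep_rows.append(
                        {"INV_1": da.label, "INV_2": db.label,
                         "Gtotal": rg.G_total, "dftotal": rg.df_total, "ptotal": rg.p_total,
                         "Gpooled": rg.G_pooled, "dfpooled": rg.df_pooled, "ppooled": rg.p_pooled,
                         "Ghet": rg.G_het, "dfhet": rg.df_het, "phet": rg.p_het}
                    )
    replicated = pd.DataFrame(rep_rows)
    _write(replicated, out_dir, "replicated_g.tsv")

    sd_all = pd.concat(sd_frames, ignore_index=True) if sd_frames else pd.DataFrame()
    per_locus_frames, corr = [], {}
    if not sd_all.empty and not omnibus.empty:
        for cross_id, sd_grp in sd_all.groupby("cross"):
            om_grp = omnibus[omnibus["cross"] == cross_id]
            pl, _ = sdv_interaction_summary(sd_grp, om_grp, level=cfg.level)
            pl.insert(0, "cross", cross_id)
            per_locus_frames.append(pl)
        pooled = pd.concat(per_locus_frames, ignore_index=True) if per_locus_frames else pd.DataFrame()
        if not pooled.empty and pooled["SDV"].nunique() > 1:
            from scipy import stats as _st

            rho, p = _st.spearmanr(pooled["SDV"], pooled["n_significant"])
            corr["rho_count"], corr["p_count"] = float(rho), float(p)
            rho, p = _st.spearmanr(pooled["SDV"], pooled["mean_p"])
            corr["rho_meanp"], corr["p_meanp"] = float(rho), float(p)
        _write(pooled, out_dir, "sdv_interaction.tsv")
    else:
        pooled = pd.DataFrame()

    log["sdv_correlations"] = corr
    if out_dir is not None:
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))

    return {
        "sd": sd_all,
        "omnibus": omnibus,
        "contrasts": contrasts,
        "networks": networks,
        "motifs": motifs,
        "replicated_g": replicated,
        "sdv_interaction": pooled,
        "log": log,
    }
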
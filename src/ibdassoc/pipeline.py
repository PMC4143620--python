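"""End-to-end pipeline: simulate/load -> pair IBD -> region scan -> association.

The pipeline reproduces the two-track workflow of an IBD-guided association
study: IBD states are inferred on a (optionally LD-pruned) marker panel for
all unrelated case-case and case-control pairs, regions with excess
case-case sharing are selected, and each region is tested against the
longitudinal phenotype on the dense genotype sources (dosages, "DOS", and
hard calls, "WGS"). All four table-shaped artifacts plus a run manifest are
written to the output directory; identical seed and config give identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ibdassoc import io as iomod
from ibdassoc.association import test_regions
from ibdassoc.hmm import IBDModelParams, posterior_decode_pairs, sharing_summary, summary_table
from ibdassoc.pedigree import Pedigree, relationship_matrix, unrelated_pairs
from ibdassoc.regions import (PruneConfig, RegionSelectionConfig, annotate_regions,
                              call_regions, centered_excess, ibd_rates, ld_prune,
                              maf_filter, regions_bed, regions_table)
from ibdassoc.simulate import SimConfig, dichotomize_hypertension, simulate_dataset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one run needs: data source, model knobs, seed, output dir.

    Either ``simulate`` holds a :class:`SimConfig`, or ``paths`` holds
    ``{"vcf": ..., "fam": ..., "pheno": ..., "map": ...}`` for real files.
    """

    out_dir: str | Path = "run"
    seed: int = 0
    simulate: SimConfig | None = None
    paths: dict | None = None
    ibd: IBDModelParams = field(default_factory=IBDModelParams)
    prune: PruneConfig = field(default_factory=PruneConfig)
    do_prune: bool = True
    select: RegionSelectionConfig = field(default_factory=RegionSelectionConfig)
    rare_maf_max: float = 0.01
    with_rare: bool = True
    hypertension_threshold: float = 90.0
    max_pairs_per_group: int | None = None   # optional subsample for huge cohorts

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulate") is not None and not isinstance(d["simulate"], SimConfig):
            sim = dict(d["simulate"])
            if "sigma_e" in sim:
                sim["sigma_e"] = np.asarray(sim["sigma_e"], dtype=float)
            if "family_template" in sim:
                from ibdassoc.simulate import FamilyTemplate
                sim["family_template"] = FamilyTemplate(**sim["family_template"])
            if "causal_region" in sim:
                sim["causal_region"] = tuple(sim["causal_region"])
            d["simulate"] = SimConfig(**sim)
        for key, typ in (("ibd", IBDModelParams), ("prune", PruneConfig),
                         ("select", RegionSelectionConfig)):
            if key in d and d[key] is not None and not isinstance(d[key], typ):
                d[key] = typ(**d[key])
        if d.get("simulate") is None and d.get("paths") is None:
            raise ValueError("config needs either a 'simulate' block or 'paths'")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def normalized(self) -> dict:
        """Plain-data form of the config (stable for hashing/round-trips)."""
        def conv(x):
            if isinstance(x, (SimConfig, IBDModelParams, PruneConfig,
                              RegionSelectionConfig)):
                return {k: conv(v) for k, v in vars(x).items()}
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, Path):
                return str(x)
            if isinstance(x, tuple):
                return list(x)
            if hasattr(x, "__dataclass_fields__"):
                return {k: conv(v) for k, v in vars(x).items()}
            return x
        return {k: conv(v) for k, v in vars(self).items()}

    def content_hash(self) -> str:
        payload = json.dumps(self.normalized(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate is not None:
        sim = cfg.simulate
        if sim.seed != cfg.seed:
            sim = SimConfig(**{**vars(sim), "seed": cfg.seed})
        ds = simulate_dataset(sim)
        status = dichotomize_hypertension(ds.phenotypes, sim.hypertension_threshold)
        return (ds.pedigree, ds.panel, ds.genotypes, ds.dosages,
                ds.phenotypes, ds.ids, status)
    p = cfg.paths
    panel, G, D, ids = iomod.read_vcf(p["vcf"])
    panel = iomod.attach_cm(panel, p.get("map"))
    ped, fam_status = Pedigree.from_fam(p["fam"])
    pheno = iomod.read_phenotypes(p["pheno"])
    if all(s == "missing" for s in fam_status.values()):
        fam_status = dichotomize_hypertension(pheno, cfg.hypertension_threshold)
    return ped, panel, G, (D if D is not None else G.astype(float)), pheno, ids, fam_status


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run simulate/load -> IBD -> region selection -> association.

    Writes ``pairs.tsv``, ``ibd_summary.tsv``, ``regions.tsv`` (+ ``.bed``),
    ``association.tsv`` and ``manifest.json`` under ``cfg.out_dir`` and
    returns that directory. Raises :class:`PipelineError` naming the failed
    stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    ped, panel, G, D, pheno, ids, status = stage("load", lambda: _load_inputs(cfg))

    def mk_pairs():
        pairs = unrelated_pairs(ped, status)
        df = pd.DataFrame(
            [(a, b, "caca") for a, b in pairs.caca]
            + [(a, b, "caco") for a, b in pairs.caco],
            columns=["id_a", "id_b", "group"])
        df.to_csv(out / "pairs.tsv", sep="\t", index=False)
        return pairs

    pairs = stage("pairs", mk_pairs)
    if not pairs.caca or not pairs.caco:
        raise PipelineError("stage 'pairs' failed: need both CaCa and CaCo pairs")

    def mk_panel():
        keep = maf_filter(G, panel, cfg.prune.maf_min)
        if cfg.do_prune:
            kept2 = ld_prune(G[:, keep], panel.iloc[keep].reset_index(drop=True),
                             cfg.prune)
            keep = keep[kept2]
        return keep

    ibd_idx = stage("marker_filter", mk_panel)
    ibd_panel = panel.iloc[ibd_idx].reset_index(drop=True)
    pos = {iid: k for k, iid in enumerate(ids)}

    def decode_group(plist):
        if cfg.max_pairs_per_group is not None and len(plist) > cfg.max_pairs_per_group:
            sel = rng.choice(len(plist), cfg.max_pairs_per_group, replace=False)
            plist = [plist[i] for i in sorted(sel)]
        ga = np.stack([G[pos[a]][ibd_idx] for a, _ in plist])
        gb = np.stack([G[pos[b]][ibd_idx] for _, b in plist])
        return posterior_decode_pairs(cfg.ibd, ibd_panel, ga, gb, plist)

    def mk_ibd():
        tracks = {"caca": decode_group(pairs.caca), "caco": decode_group(pairs.caco)}
        tab = summary_table([sharing_summary(tracks[g], g) for g in ("caca", "caco")])
        tab.to_csv(out / "ibd_summary.tsv", sep="\t", index=False, float_format="%.6g")
        return tracks

    tracks = stage("ibd", mk_ibd)

    def mk_regions():
        rates = ibd_rates(tracks, ibd_panel)
        centered = centered_excess(rates)
        regs = call_regions(centered, ibd_panel, cfg.select)
        regs = annotate_regions(regs, panel, G, cfg.rare_maf_max)
        regions_table(regs).to_csv(out / "regions.tsv", sep="\t", index=False,
                                   float_format="%.6g")
        regions_bed(regs).to_csv(out / "regions.bed", sep="\t", index=False,
                                 header=False)
        return regs

    regs = stage("select_regions", mk_regions)

    def mk_assoc():
        R = relationship_matrix(ped, ids)
        frames = []
        for label, src in (("DOS", D), ("WGS", G)):
            res = test_regions(regs, pheno, src, panel, ids, R,
                               rare_maf_max=cfg.rare_maf_max,
                               with_rare=cfg.with_rare)
            res.insert(1, "dataset", label)
            frames.append(res)
        tab = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame())
        tab.to_csv(out / "association.tsv", sep="\t", index=False,
                   float_format="%.6g")
        return tab

    assoc = stage("associate", mk_assoc)

    def mk_manifest():
        import scipy
        import ibdassoc
        manifest = {
            "config_hash": cfg.content_hash(),
            "config": cfg.normalized(),
            "seed": cfg.seed,
            "versions": {"ibdassoc": ibdassoc.__version__,
                         "numpy": np.__version__, "scipy": scipy.__version__,
                         "pandas": pd.__version__},
            "n_caca_pairs": len(pairs.caca),
            "n_caco_pairs": len(pairs.caco),
            "n_ibd_markers": int(len(ibd_idx)),
            "n_regions": int(len(regs)),
            "outputs": ["pairs.tsv", "ibd_summary.tsv", "regions.tsv",
                        "regions.bed", "association.tsv"],
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    stage("manifest", mk_manifest)
    logger.info("pipeline complete: %d regions, %d association rows",
                len(regs), len(assoc))
    return out
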
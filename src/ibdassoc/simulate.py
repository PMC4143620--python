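"""Synthetic family datasets: pedigrees, genotypes, dosages and phenotypes.

The generator emulates, at desk scale, the ingredients of a longitudinal
family sequencing study: a set of multigeneration pedigrees, founder
haplotypes drawn either independently per marker (no LD) or from a finite
haplotype pool (LD decaying with pool diversity), gene-dropping with
recombination on a cM map (Haldane), rare causal variants riding on a shared
ancestral founder segment inside a designated region, imputation-style dosage
noise, and diastolic-blood-pressure-like longitudinal phenotypes generated
from the same mixed model the association stage fits:

    DBP_ijt = b0 + b_age age + b_smoke smoke + beta2 load + beta3 s + u_ij + e_ijt

with family effects ``u_i ~ MVN(0, sigma_u^2 R_i)`` and per-individual
residuals ``MVN(0, Sigma_e)`` over the T time points. Founder-origin labels
are propagated through the gene drop so the *true* IBD state of any pair at
any marker is recoverable, which is what makes the IBD-HMM testable.

Default parameter values state a realistic world: 20 families, four exam
waves 5 years apart, mean DBP around 85 mmHg (~30% hypertension prevalence,
typical of family studies ascertained for blood pressure), family variance
10.6 mmHg^2, a
residual covariance with variance 60 mmHg^2 and serial correlation 0.5, and a
clinical hypertension cutoff of 90 mmHg at the first exam.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from ibdassoc.pedigree import Individual, Pedigree, relationship_matrix

MISSING = -1


def _default_sigma_e(T: int = 4, var: float = 60.0, rho: float = 0.5) -> np.ndarray:
    """AR(1)-like residual covariance: serial correlation decaying with lag."""
    lags = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
    return var * rho ** lags


@dataclass(frozen=True)
class FamilyTemplate:
    """Family shape: a founder couple, their children with married-in
    spouses, and grandchildren per child couple. ``generations=2`` stops at
    the children (no spouses, no grandchildren)."""

    generations: int = 3
    n_children: int = 3
    n_grandchildren: int = 2

    def __post_init__(self):
        if self.generations not in (2, 3):
            raise ValueError("generations must be 2 or 3")
        if self.n_children < 1 or self.n_grandchildren < 0:
            raise ValueError("invalid sibship sizes")

    @property
    def size(self) -> int:
        if self.generations == 2:
            return 2 + self.n_children
        return 2 + 2 * self.n_children + self.n_children * self.n_grandchildren


@dataclass
class SimConfig:
    """Full description of one synthetic dataset (seed-deterministic)."""

    n_families: int = 20
    family_template: FamilyTemplate = field(default_factory=FamilyTemplate)
    n_markers: int = 784
    map_length_cm: float = 220.0
    allele_freq_spectrum: tuple = ("uniform", 0.05, 0.5)
    ld_mode: str = "independent"            # or "haplotype_pool"
    pool_size: int = 8
    causal_region: tuple[float, float] = (100.0, 110.0)  # cM interval
    n_causal: int = 5
    causal_maf: float = 0.04
    n_rare_background: int = 40
    effect_beta2: float = 0.0               # phenotype units per unit EB-load
    effect_beta3: float = 0.0               # phenotype units per rare allele
    beta0: float = 70.0
    beta_age: float = 0.3
    beta_smoke: float = 2.0
    sigma_u2: float = 10.6
    sigma_e: np.ndarray = field(default_factory=_default_sigma_e)
    n_timepoints: int = 4
    age_step: float = 5.0
    smoke_prob: float = 0.25
    hypertension_threshold: float = 90.0
    dosage_noise_sd: float = 0.1
    genotyping_error: float = 0.0
    chrom: str = "3"
    seed: int = 0

    def __post_init__(self):
        Se = np.asarray(self.sigma_e, dtype=float)
        if Se.shape != (self.n_timepoints, self.n_timepoints):
            raise ValueError("sigma_e must be T x T")
        if not np.allclose(Se, Se.T) or np.any(np.linalg.eigvalsh(Se) <= 0):
            raise ValueError("sigma_e must be symmetric positive definite")
        if self.sigma_u2 < 0:
            raise ValueError("sigma_u2 must be >= 0")
        if not 0 <= self.causal_maf <= 0.5:
            raise ValueError("causal_maf must be in [0, 0.5]")
        if self.dosage_noise_sd < 0:
            raise ValueError("dosage_noise_sd must be >= 0")
        if self.ld_mode not in ("independent", "haplotype_pool"):
            raise ValueError("ld_mode must be 'independent' or 'haplotype_pool'")
        if self.ld_mode == "haplotype_pool" and self.pool_size < 2:
            raise ValueError("pool_size must be >= 2 in haplotype_pool mode")


@dataclass
class SimulatedDataset:
    """A simulated cohort with full generative truth attached."""

    config: SimConfig
    pedigree: Pedigree
    ids: list[str]                  # row order of the genotype matrices
    panel: pd.DataFrame             # marker_id, chrom, bp, cm, ref, alt, freq, is_causal
    haplotypes: np.ndarray          # (n_ind, 2, M) alleles
    founder_labels: np.ndarray      # (n_ind, 2, M) founder-haplotype origin
    genotypes: np.ndarray           # (n_ind, M) hard calls
    dosages: np.ndarray             # (n_ind, M) in [0, 2]
    phenotypes: pd.DataFrame        # long format
    truth: dict

    def true_ibd_state(self, id_a: str, id_b: str) -> np.ndarray:
        """Per-marker true IBD allele-sharing count (0/1/2) from descent labels."""
        ia, ib = self.ids.index(id_a), self.ids.index(id_b)
        a1, a2 = self.founder_labels[ia]
        b1, b2 = self.founder_labels[ib]
        straight = (a1 == b1) & (a2 == b2)
        crossed = (a1 == b2) & (a2 == b1)
        ibd2 = straight | crossed
        any_match = (a1 == b1) | (a1 == b2) | (a2 == b1) | (a2 == b2)
        return np.where(ibd2, 2, np.where(any_match, 1, 0)).astype(np.int8)


# ---------------------------------------------------------------------------
# pedigree and marker panel
# ---------------------------------------------------------------------------

def simulate_pedigree_set(cfg: SimConfig) -> Pedigree:
    """``n_families`` disjoint copies of the family template, unique ids."""
    t = cfg.family_template
    inds: list[Individual] = []
    for f in range(1, cfg.n_families + 1):
        fam = f"F{f:03d}"

        def iid(k):
            return f"{fam}-I{k:03d}"

        k = 1
        father, mother = iid(k), iid(k + 1)
        k += 2
        inds.append(Individual(father, fam, None, None, "male"))
        inds.append(Individual(mother, fam, None, None, "female"))
        for c in range(t.n_children):
            child = iid(k); k += 1
            child_sex = "male" if c % 2 == 0 else "female"
            inds.append(Individual(child, fam, father, mother, child_sex))
            if t.generations == 3:
                spouse = iid(k); k += 1
                spouse_sex = "female" if child_sex == "male" else "male"
                inds.append(Individual(spouse, fam, None, None, spouse_sex))
                dad, mom = (child, spouse) if child_sex == "male" else (spouse, child)
                for _ in range(t.n_grandchildren):
                    gc = iid(k); k += 1
                    inds.append(Individual(gc, fam, dad, mom, "male" if k % 2 else "female"))
    return Pedigree(inds)


def _spectrum_draw(spec: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size=size)
    if kind == "beta":
        return np.clip(rng.beta(spec[1], spec[2], size=size), 1e-4, 1 - 1e-4)
    raise ValueError(f"unknown allele frequency spectrum {spec!r}")


_BASES = np.array(list("ACGT"))


def build_panel(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Marker panel: common markers plus rare background and causal variants.

    Positions are uniform on the cM map with bp = cM x 1 Mb; causal markers
    sit inside ``causal_region`` and carry the nominal frequency
    ``causal_maf`` (realized only through carrier haplotypes).
    """
    cm_common = rng.uniform(0, cfg.map_length_cm, size=cfg.n_markers)
    f_common = _spectrum_draw(cfg.allele_freq_spectrum, cfg.n_markers, rng)
    cm_rare = rng.uniform(0, cfg.map_length_cm, size=cfg.n_rare_background)
    f_rare = rng.uniform(0.002, 0.01, size=cfg.n_rare_background)
    lo, hi = cfg.causal_region
    cm_causal = rng.uniform(lo, hi, size=cfg.n_causal)
    f_causal = np.full(cfg.n_causal, cfg.causal_maf)

    cm = np.concatenate([cm_common, cm_rare, cm_causal])
    freq = np.concatenate([f_common, f_rare, f_causal])
    causal = np.concatenate([np.zeros(cfg.n_markers + cfg.n_rare_background, bool),
                             np.ones(cfg.n_causal, bool)])
    order = np.argsort(cm, kind="stable")
    cm, freq, causal = cm[order], freq[order], causal[order]
    bp = np.maximum(1, np.round(cm * 1e6)).astype(np.int64)
    bp = np.maximum.accumulate(bp + np.arange(len(bp)))  # strictly increasing
    ref = _BASES[rng.integers(0, 4, size=len(cm))]
    alt = np.array([_BASES[(list(_BASES).index(r) + 1 + rng.integers(0, 3)) % 4]
                    for r in ref])
    return pd.DataFrame({
        "marker_id": [f"m{i + 1:05d}" for i in range(len(cm))],
        "chrom": cfg.chrom, "bp": bp, "cm": cm,
        "ref": ref, "alt": alt, "freq": freq, "is_causal": causal,
    })


# ---------------------------------------------------------------------------
# haplotypes and gene dropping
# ---------------------------------------------------------------------------

def draw_founder_haplotypes(cfg: SimConfig, n_founders: int, panel: pd.DataFrame,
                            rng: np.random.Generator) -> np.ndarray:
    """Founder haplotypes (2 per founder) as a (2 * n_founders, M) 0/1 array.

    ``independent`` mode draws each allele Bernoulli(p_m) independently;
    ``haplotype_pool`` mode draws each founder haplotype uniformly from a
    fixed pool of ``pool_size`` distinct haplotypes, inducing LD. Causal
    markers start at 0 and are populated by :func:`inject_causal_segment`.
    """
    p = panel["freq"].to_numpy().copy()
    p[panel["is_causal"].to_numpy()] = 0.0
    n_hap = 2 * n_founders
    if cfg.ld_mode == "independent":
        haps = (rng.random((n_hap, len(p))) < p).astype(np.int8)
    else:
        pool = (rng.random((cfg.pool_size, len(p))) < p).astype(np.int8)
        haps = pool[rng.integers(0, cfg.pool_size, size=n_hap)]
    return haps


def inject_causal_segment(cfg: SimConfig, panel: pd.DataFrame, haps: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Make a fraction ``causal_maf`` of founder haplotypes carriers.

    A carrier haplotype has its alleles over the causal cM interval replaced
    by one shared ancestral segment that carries the alternate allele at
    every causal marker — so carriers across families share a long identical
    haplotype around the causal variants, the signature IBD mapping detects.
    Returns the carrier indicator per founder haplotype.
    """
    cm = panel["cm"].to_numpy()
    lo, hi = cfg.causal_region
    in_region = (cm >= lo) & (cm <= hi)
    causal = panel["is_causal"].to_numpy()
    segment = (rng.random(int(in_region.sum())) < panel.loc[in_region, "freq"].to_numpy())
    segment = segment.astype(np.int8)
    segment[causal[in_region]] = 1
    carrier = rng.random(haps.shape[0]) < cfg.causal_maf
    haps[np.ix_(carrier, np.flatnonzero(in_region))] = segment
    return carrier


def haldane(d_cm: np.ndarray) -> np.ndarray:
    """Recombination fraction r = (1 - exp(-2 d / 100)) / 2 for d in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def _meiosis(hap_pair: np.ndarray, label_pair: np.ndarray, rec: np.ndarray,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: a mosaic of the parent's two haplotypes (Haldane crossovers)."""
    M = hap_pair.shape[1]
    switches = rng.random(M - 1) < rec
    phase = np.empty(M, dtype=np.int8)
    phase[0] = rng.integers(0, 2)
    phase[1:] = (phase[0] + np.cumsum(switches)) % 2
    rows = np.arange(M)
    return hap_pair[phase, rows], label_pair[phase, rows]


def gene_drop(ped: Pedigree, founder_haps: np.ndarray, cm: np.ndarray,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Drop founder haplotypes through the pedigree with recombination.

    Founders take consecutive rows of ``founder_haps`` (in pedigree founder
    order); every founder haplotype gets a unique origin label that is
    propagated, so descent (true IBD) is recoverable. Returns
    ``(haplotypes, labels, genotypes, ids)`` with shapes (n, 2, M), (n, 2, M)
    and (n, M); ids give the row order.
    """
    if np.any(np.diff(cm) < 0):
        raise ValueError("map positions must be non-decreasing")
    ids = ped.ids
    pos = {iid: k for k, iid in enumerate(ids)}
    M = founder_haps.shape[1]
    n = len(ids)
    haps = np.zeros((n, 2, M), dtype=np.int8)
    labels = np.zeros((n, 2, M), dtype=np.int32)
    rec = haldane(np.diff(cm))

    founder_row = 0
    for iid in ped.topological_order():
        i = pos[iid]
        ind = ped[iid]
        if ind.father_id is None and ind.mother_id is None:
            haps[i, 0] = founder_haps[2 * founder_row]
            haps[i, 1] = founder_haps[2 * founder_row + 1]
            labels[i, 0] = 2 * founder_row + 1
            labels[i, 1] = 2 * founder_row + 2
            founder_row += 1
        elif ind.father_id is None or ind.mother_id is None:
            raise ValueError(f"{iid}: gene_drop requires both parents or neither")
        else:
            fi, mi = pos[ind.father_id], pos[ind.mother_id]
            haps[i, 0], labels[i, 0] = _meiosis(haps[fi], labels[fi], rec, rng)
            haps[i, 1], labels[i, 1] = _meiosis(haps[mi], labels[mi], rec, rng)
    genotypes = haps.sum(axis=1, dtype=np.int8)
    return haps, labels, genotypes, ids


def apply_genotyping_error(genotypes: np.ndarray, freq: np.ndarray,
                           error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Replace each genotype, with probability ``error_rate``, by an HWE draw."""
    if error_rate <= 0:
        return genotypes
    g = genotypes.copy()
    hit = rng.random(g.shape) < error_rate
    u = rng.random(g.shape)
    p = np.broadcast_to(freq, g.shape)
    hwe_draw = (u > (1 - p) ** 2).astype(np.int8) + (u > 1 - p ** 2).astype(np.int8)
    g[hit] = hwe_draw[hit]
    return g


# ---------------------------------------------------------------------------
# phenotypes, dosages, case status
# ---------------------------------------------------------------------------

def genetic_covariates(cfg: SimConfig, genotypes: np.ndarray,
                       panel: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """The generative region covariates: standardized load and rare count.

    ``load`` is the mean standardized genotype over the causal region's
    common (MAF >= 0.05) markers — the quantity the EB stage later
    estimates; ``s`` is the causal rare-allele count per individual.
    """
    cm = panel["cm"].to_numpy()
    lo, hi = cfg.causal_region
    in_region = (cm >= lo) & (cm <= hi)
    g = np.asarray(genotypes, dtype=float)
    p_hat = g.mean(axis=0) / 2.0
    common = in_region & (np.minimum(p_hat, 1 - p_hat) >= 0.05)
    if common.any():
        z = (g[:, common] - 2 * p_hat[common]) / np.sqrt(
            2 * p_hat[common] * (1 - p_hat[common]))
        load = z.mean(axis=1)
    else:
        load = np.zeros(g.shape[0])
    s = g[:, panel["is_causal"].to_numpy()].sum(axis=1)
    return load, s


def simulate_phenotypes(cfg: SimConfig, ped: Pedigree, genotypes: np.ndarray,
                        panel: pd.DataFrame, ids: list[str],
                        rng: np.random.Generator) -> pd.DataFrame:
    """Longitudinal DBP-like phenotypes from the generative mixed model.

    The genetic signal is ``effect_beta2`` times the standardized mean
    genotype over the causal region's common markers (the quantity the EB
    stage estimates) plus ``effect_beta3`` times the causal rare-allele
    count. Family effects are MVN(0, sigma_u^2 R_i); residuals MVN(0,
    Sigma_e) over time points; age increases by ``age_step`` per wave.
    """
    T = cfg.n_timepoints
    Se = np.asarray(cfg.sigma_e, dtype=float)
    R = relationship_matrix(ped, ids)
    n = len(ids)

    load, s = genetic_covariates(cfg, genotypes, panel)

    u = np.zeros(n)
    id_pos = {iid: k for k, iid in enumerate(ids)}
    if cfg.sigma_u2 > 0:
        for fam in ped.families:
            members = ped.members_of(fam)
            idx = np.array([id_pos[m] for m in members])
            Rf = R.loc[members, members].to_numpy()
            Lf = np.linalg.cholesky(cfg.sigma_u2 * Rf + 1e-10 * np.eye(len(members)))
            u[idx] = Lf @ rng.standard_normal(len(members))

    Le = np.linalg.cholesky(Se)
    e = rng.standard_normal((n, T)) @ Le.T
    age0 = np.clip(rng.normal(50.0, 10.0, size=n), 20.0, 90.0)
    smoke = (rng.random(n) < cfg.smoke_prob).astype(int)

    rows = []
    for k, iid in enumerate(ids):
        fam = ped[iid].family_id
        for t in range(T):
            age = age0[k] + cfg.age_step * t
            dbp = (cfg.beta0 + cfg.beta_age * age + cfg.beta_smoke * smoke[k]
                   + cfg.effect_beta2 * load[k] + cfg.effect_beta3 * s[k]
                   + u[k] + e[k, t])
            rows.append((fam, iid, t + 1, dbp, age, smoke[k]))
    pheno = pd.DataFrame(rows, columns=["family_id", "individual_id",
                                        "timepoint", "dbp", "age", "smoke"])
    first = pheno[pheno["timepoint"] == 1].set_index("individual_id")["dbp"]
    pheno["hypertension"] = (pheno["individual_id"].map(first)
                             >= cfg.hypertension_threshold).astype(int)
    return pheno


def dichotomize_hypertension(pheno: pd.DataFrame,
                             threshold: float) -> dict[str, str]:
    """Case status from first-time-point DBP: case iff DBP_1 >= threshold.

    The boundary is inclusive; individuals without a first-wave measurement
    get status ``"missing"``.
    """
    status: dict[str, str] = {}
    first = pheno[pheno["timepoint"] == 1]
    seen = first.dropna(subset=["dbp"]).set_index("individual_id")["dbp"]
    for iid in pheno["individual_id"].unique():
        if iid in seen.index:
            status[iid] = "case" if seen[iid] >= threshold else "control"
        else:
            status[iid] = "missing"
    return status


def emulate_dosages(genotypes: np.ndarray, dosage_noise_sd: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Imputation-style dosages: clip(g + N(0, sd), 0, 2)."""
    if dosage_noise_sd < 0:
        raise ValueError("dosage_noise_sd must be >= 0")
    g = genotypes.astype(float)
    if dosage_noise_sd == 0:
        return g
    return np.clip(g + rng.normal(0, dosage_noise_sd, size=g.shape), 0.0, 2.0)


# ---------------------------------------------------------------------------
# orchestration and output
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate a full synthetic cohort; byte-identical under a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree_set(cfg)
    panel = build_panel(cfg, rng)
    founders = ped.founders()
    haps = draw_founder_haplotypes(cfg, len(founders), panel, rng)
    carrier = inject_causal_segment(cfg, panel, haps, rng)
    hap_arr, labels, genotypes, ids = gene_drop(
        ped, haps, panel["cm"].to_numpy(), rng)
    genotypes = apply_genotyping_error(genotypes, panel["freq"].to_numpy(),
                                       cfg.genotyping_error, rng)
    dosages = emulate_dosages(genotypes, cfg.dosage_noise_sd, rng)
    pheno = simulate_phenotypes(cfg, ped, genotypes, panel, ids, rng)
    truth = {
        "causal_marker_ids": panel.loc[panel["is_causal"], "marker_id"].tolist(),
        "causal_region_cm": list(cfg.causal_region),
        "n_carrier_founder_haplotypes": int(carrier.sum()),
        "effect_beta2": cfg.effect_beta2,
        "effect_beta3": cfg.effect_beta3,
        "beta0": cfg.beta0, "beta_age": cfg.beta_age, "beta_smoke": cfg.beta_smoke,
        "sigma_u2": cfg.sigma_u2,
        "sigma_e": np.asarray(cfg.sigma_e).tolist(),
        "seed": cfg.seed,
    }
    return SimulatedDataset(config=cfg, pedigree=ped, ids=ids, panel=panel,
                            haplotypes=hap_arr, founder_labels=labels,
                            genotypes=genotypes, dosages=dosages,
                            phenotypes=pheno, truth=truth)


def write_dataset(ds: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Write VCF (GT + DS), PLINK PED/MAP/FAM, phenotype TSV and truth JSON."""
    from ibdassoc import io as iomod

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "ped": out / "genotypes.ped",
        "map": out / "genotypes.map",
        "fam": out / "pedigree.fam",
        "pheno": out / "phenotypes.tsv",
        "truth": out / "truth.json",
    }
    iomod.write_vcf(paths["vcf"], ds.panel, ds.ids, ds.genotypes, ds.dosages)
    iomod.write_ped_map(paths["ped"], paths["map"], ds.pedigree, ds.panel,
                        ds.ids, ds.genotypes)
    status = dichotomize_hypertension(ds.phenotypes,
                                      ds.config.hypertension_threshold)
    ds.pedigree.to_fam(paths["fam"], status)
    iomod.write_phenotypes(paths["pheno"], ds.phenotypes)
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
    return paths
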
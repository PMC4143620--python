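"""Readers and writers for VCF, PLINK PED/MAP and phenotype tables.

Hard genotypes round-trip bit-exactly through write/read; dosages are
formatted with 3 decimals (re-read within 5e-4). VCF reading goes through
cyvcf2; multiallelic records are skipped with a warning. Positions are
1-based; missing genotypes use -1 in matrices and ./. or "0 0" on disk.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd

from ibdassoc.pedigree import Pedigree

MISSING = -1


def write_vcf(path, panel: pd.DataFrame, ids, genotypes: np.ndarray,
              dosages: np.ndarray | None = None) -> None:
    """Write a VCF 4.2 with GT (and optionally DS) per sample."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if len(panel):
            chroms = pd.unique(panel["chrom"])
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dosages is not None:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                     'Description="Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        fmt = "GT:DS" if dosages is not None else "GT"
        for m in range(len(panel)):
            row = panel.iloc[m]
            fields = []
            for k in range(len(ids)):
                g = int(genotypes[k, m])
                cell = gt_str.get(g, "./.")
                if dosages is not None:
                    cell += f":{dosages[k, m]:.3f}"
                fields.append(cell)
            fh.write(f"{row['chrom']}\t{int(row['bp'])}\t{row['marker_id']}\t"
                     f"{row['ref']}\t{row['alt']}\t.\t.\t.\t{fmt}\t"
                     + "\t".join(fields) + "\n")


def read_vcf(path) -> tuple[pd.DataFrame, np.ndarray, np.ndarray | None, list[str]]:
    """Read a VCF into (panel, genotypes, dosages or None, sample ids).

    Genotypes are alt-allele counts with -1 missing; the panel carries
    marker_id, chrom, bp, ref, alt and the sample alt frequency ``freq``.
    Multiallelic records are skipped with a warning (count reported).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, gts, doses = [], [], []
    n_multi = 0
    has_ds = False
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        try:
            g = np.array([(gt[0] + gt[1]) if (gt[0] >= 0 and gt[1] >= 0) else MISSING
                          for gt in v.genotypes], dtype=np.int8)
        except Exception:  # DS-only records carry no GT
            g = np.full(len(ids), MISSING, dtype=np.int8)
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            has_ds = True
            doses.append(np.asarray(ds, dtype=float).reshape(-1))
        else:
            doses.append(None)
        gts.append(g)
        rows.append({"marker_id": v.ID or f"{v.CHROM}:{v.POS}", "chrom": v.CHROM,
                     "bp": v.POS, "ref": v.REF, "alt": v.ALT[0]})
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic records", stacklevel=2)
    panel = pd.DataFrame(rows, columns=["marker_id", "chrom", "bp", "ref", "alt"])
    G = np.stack(gts, axis=1) if gts else np.zeros((len(ids), 0), dtype=np.int8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        Gf = np.where(G < 0, np.nan, G.astype(float))
        panel["freq"] = np.nanmean(Gf, axis=0) / 2.0 if len(panel) else []
    D = None
    if has_ds and all(d is not None for d in doses):
        D = np.stack(doses, axis=1)
    return panel, G, D, ids


def attach_cm(panel: pd.DataFrame, map_path=None) -> pd.DataFrame:
    """Attach cM positions from a MAP file, or default to 1 cM per Mb."""
    panel = panel.copy()
    if map_path is not None:
        m = read_map(map_path).set_index("marker_id")
        panel["cm"] = panel["marker_id"].map(m["cm"])
        if panel["cm"].isna().any():
            raise ValueError("map file lacks positions for some VCF markers")
    else:
        panel["cm"] = panel["bp"].astype(float) / 1e6
    return panel


def write_ped_map(ped_path, map_path, pedigree: Pedigree, panel: pd.DataFrame,
                  ids, genotypes: np.ndarray) -> None:
    """PLINK text PED/MAP; alleles spelled with the panel's ref/alt bases."""
    with open(map_path, "w") as fh:
        for _, r in panel.iterrows():
            fh.write(f"{r['chrom']} {r['marker_id']} {r['cm']:.6f} {int(r['bp'])}\n")
    ref = panel["ref"].to_numpy()
    alt = panel["alt"].to_numpy()
    sex_out = {"male": "1", "female": "2", "unknown": "0"}
    with open(ped_path, "w") as fh:
        for k, iid in enumerate(ids):
            ind = pedigree[iid]
            lead = [ind.family_id, iid, ind.father_id or "0",
                    ind.mother_id or "0", sex_out[ind.sex], "0"]
            alleles = []
            for m in range(len(panel)):
                g = int(genotypes[k, m])
                if g == 0:
                    a, b = ref[m], ref[m]
                elif g == 1:
                    a, b = ref[m], alt[m]
                elif g == 2:
                    a, b = alt[m], alt[m]
                else:
                    a, b = "0", "0"
                alleles += [a, b]
            fh.write(" ".join(lead + alleles) + "\n")


def read_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", header=None,
                       names=["chrom", "marker_id", "cm", "bp"],
                       dtype={"chrom": str})


def read_ped_map(ped_path, map_path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read PLINK text PED/MAP into (panel, genotype matrix, ids).

    PED does not record which allele is the reference, so the more frequent
    letter per marker is taken as ref and counts are of the other (alt)
    letter. Allele letters themselves round-trip exactly through the
    package's own writer.
    """
    panel = read_map(map_path)
    rows = []
    ids = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            need = 6 + 2 * len(panel)
            if len(parts) != need:
                raise ValueError(f"{ped_path}:{lineno}: expected {need} fields, "
                                 f"got {len(parts)}")
            ids.append(parts[1])
            rows.append(parts[6:])
    M = len(panel)
    n = len(ids)
    a1 = np.empty((n, M), dtype="U1")
    a2 = np.empty((n, M), dtype="U1")
    for k, r in enumerate(rows):
        a1[k] = r[0::2]
        a2[k] = r[1::2]
    G = np.full((n, M), MISSING, dtype=np.int8)
    refs, alts = [], []
    for m in range(M):
        obs = np.concatenate([a1[:, m], a2[:, m]])
        obs = obs[obs != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) == 0:
            refs.append("N"); alts.append("N")
            continue
        order = np.argsort(-counts, kind="stable")
        ref = uniq[order[0]]
        alt = uniq[order[1]] if len(uniq) > 1 else "N"
        refs.append(ref); alts.append(alt)
        miss = (a1[:, m] == "0") | (a2[:, m] == "0")
        G[:, m] = (a1[:, m] == alt).astype(np.int8) + (a2[:, m] == alt).astype(np.int8)
        G[miss, m] = MISSING
    panel = panel.copy()
    panel["ref"] = refs
    panel["alt"] = alts
    with np.errstate(invalid="ignore"):
        Gf = np.where(G < 0, np.nan, G.astype(float))
        panel["freq"] = np.nanmean(Gf, axis=0) / 2.0
    return panel, G, ids


def write_phenotypes(path, pheno: pd.DataFrame) -> None:
    cols = ["family_id", "individual_id", "timepoint", "dbp", "age", "smoke"]
    if "hypertension" in pheno.columns:
        cols.append("hypertension")
    pheno[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"family_id": str, "individual_id": str})
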
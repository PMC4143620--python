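"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

from ibdassoc.pedigree import Individual, Pedigree


@pytest.fixture
def founder_quartet():
    """Two families, each a founder case-control couple (all kinship 0)."""
    inds = [
        Individual("a1", "famA", sex="male"),
        Individual("a2", "famA", sex="female"),
        Individual("b1", "famB", sex="male"),
        Individual("b2", "famB", sex="female"),
    ]
    status = {"a1": "case", "a2": "control", "b1": "case", "b2": "control"}
    return Pedigree(inds), status


@pytest.fixture
def nuclear_family():
    """One founder couple with two children."""
    return Pedigree([
        Individual("f", "fam1", sex="male"),
        Individual("m", "fam1", sex="female"),
        Individual("c1", "fam1", "f", "m", "male"),
        Individual("c2", "fam1", "f", "m", "female"),
    ])


@pytest.fixture
def sib_mating_pedigree():
    """Three generations ending in an offspring of full-sib mating."""
    return Pedigree([
        Individual("g1", "fam1", sex="male"),
        Individual("g2", "fam1", sex="female"),
        Individual("s1", "fam1", "g1", "g2", "male"),
        Individual("s2", "fam1", "g1", "g2", "female"),
        Individual("x", "fam1", "s1", "s2", "male"),
    ])


def mc_kinship(ped: Pedigree, id_a: str, id_b: str, n_drops: int,
               rng: np.random.Generator) -> tuple[float, float]:
    """Monte-Carlo kinship by single-locus gene dropping (independent oracle).

    Each founder gets two globally unique alleles; every child allele is a
    uniform pick from the parent's two. The kinship estimate is the mean over
    drops of the probability that a random allele from each individual is
    identical by descent; returns (estimate, standard error).
    """
    order = ped.topological_order()
    alleles = {}
    counter = 0
    for iid in order:
        ind = ped[iid]
        if ind.father_id is None and ind.mother_id is None:
            alleles[iid] = np.full((n_drops, 2), 0, dtype=np.int32)
            alleles[iid][:, 0] = counter
            alleles[iid][:, 1] = counter + 1
            counter += 2
        else:
            a = np.empty((n_drops, 2), dtype=np.int32)
            for k, pid in enumerate((ind.father_id, ind.mother_id)):
                src = alleles[pid]
                pick = rng.integers(0, 2, size=n_drops)
                a[:, k] = src[np.arange(n_drops), pick]
            alleles[iid] = a
    A, B = alleles[id_a], alleles[id_b]
    match = np.zeros(n_drops)
    for i in range(2):
        for j in range(2):
            match += (A[:, i] == B[:, j])
    p = match / 4.0
    return float(p.mean()), float(p.std(ddof=1) / np.sqrt(n_drops))


def brute_force_posteriors(params, panel, ga, gb):
    """Posterior IBD-state probabilities by explicit path enumeration.

    Sums the joint probability of every 3^M state path with stationary
    initialization; independent of the forward-backward implementation
    (reuses only the transition/emission definitions).
    """
    from itertools import product

    from ibdassoc.hmm import _emission_table, _transition_stack

    cm = panel["cm"].to_numpy(dtype=float)
    freq = panel["freq"].to_numpy(dtype=float)
    M = len(panel)
    E = _emission_table(freq, params.epsilon)
    T = _transition_stack(params, np.diff(cm))
    pi0 = params.stationary

    def emit(m, k):
        if ga[m] < 0 or gb[m] < 0:
            return 1.0
        return E[m, k, ga[m], gb[m]]

    post = np.zeros((M, 3))
    total = 0.0
    for path in product(range(3), repeat=M):
        p = pi0[path[0]] * emit(0, path[0])
        for m in range(1, M):
            p *= T[m - 1, path[m - 1], path[m]] * emit(m, path[m])
        total += p
        for m in range(M):
            post[m, path[m]] += p
    return post / total


def make_panel(cm, freq, chrom="1"):
    """Minimal marker panel for direct HMM/region tests."""
    cm = np.asarray(cm, dtype=float)
    return pd.DataFrame({
        "marker_id": [f"m{i}" for i in range(len(cm))],
        "chrom": chrom,
        "bp": (cm * 1e6).astype(int) + 1,
        "cm": cm,
        "ref": "A", "alt": "C",
        "freq": np.asarray(freq, dtype=float),
        "is_causal": False,
    })
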
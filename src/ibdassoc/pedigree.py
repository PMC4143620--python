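"""Pedigree structure, kinship/relationship matrices, and unrelated pair lists.

The pedigree is the backbone of both halves of the workflow: it defines which
individual pairs are *unrelated* (kinship coefficient exactly 0) and therefore
eligible for the case-case / case-control IBD contrast, and it supplies the
coefficient-of-relationship matrix ``R = 2 * kinship`` that structures the family
random effect of the association mixed model.

"Unrelated" here is the literal pedigree definition — kinship 0 — which keeps
within-family founder (married-in) pairs in the pair lists, not merely pairs
from different families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MALE, FEMALE, UNKNOWN = "male", "female", "unknown"

_SEX_CODES = {"1": MALE, "2": FEMALE, "0": UNKNOWN,
              MALE: MALE, FEMALE: FEMALE, UNKNOWN: UNKNOWN}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, dangling parent, sex clash)."""


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = UNKNOWN


class Pedigree:
    """A validated set of individuals with parent links.

    Parameters
    ----------
    individuals
        Records with unique ``individual_id``. Parent ids must either be
        ``None`` (founder side) or resolve to an individual in the *same*
        family. The parent graph must be acyclic, and when parental sex is
        known, ``father_id`` must point to a male and ``mother_id`` to a
        female.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.individual_id in self._members:
                raise PedigreeError(f"duplicate individual id {ind.individual_id!r}")
            self._members[ind.individual_id] = ind
        self._validate()
        self._topo = self._topological_order()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_fam(cls, path) -> tuple["Pedigree", dict[str, str]]:
        """Read a PLINK FAM-style file.

        Whitespace-delimited columns: family, individual, father, mother,
        sex (1=male, 2=female, 0=unknown), phenotype (2=case, 1=control,
        0/-9=missing). ``0`` encodes a missing parent.

        Returns the pedigree and a ``{individual_id: status}`` mapping with
        status in ``{"case", "control", "missing"}``.
        """
        inds: list[Individual] = []
        status: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) < 6:
                    raise PedigreeError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
                fam, iid, fid, mid, sex, pheno = parts[:6]
                inds.append(Individual(
                    individual_id=iid,
                    family_id=fam,
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                    sex=_SEX_CODES.get(sex, UNKNOWN),
                ))
                status[iid] = {"2": "case", "1": "control"}.get(pheno, "missing")
        return cls(inds), status

    def to_fam(self, path, status: Mapping[str, str] | None = None) -> None:
        sex_out = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}
        pheno_out = {"case": "2", "control": "1", "missing": "0"}
        with open(path, "w") as fh:
            for ind in self:
                ph = pheno_out[(status or {}).get(ind.individual_id, "missing")]
                fh.write(" ".join([
                    ind.family_id, ind.individual_id,
                    ind.father_id or "0", ind.mother_id or "0",
                    sex_out[ind.sex], ph,
                ]) + "\n")

    # -- protocol ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self):
        return iter(self._members.values())

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._members

    def __getitem__(self, individual_id: str) -> Individual:
        try:
            return self._members[individual_id]
        except KeyError:
            raise KeyError(f"individual {individual_id!r} not in pedigree") from None

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self:
            seen.setdefault(ind.family_id, None)
        return list(seen)

    def founders(self) -> list[str]:
        return [i.individual_id for i in self
                if i.father_id is None and i.mother_id is None]

    def members_of(self, family_id: str) -> list[str]:
        return [i.individual_id for i in self if i.family_id == family_id]

    def topological_order(self) -> list[str]:
        """Ids ordered so that every parent precedes its offspring."""
        return list(self._topo)

    # -- internals ---------------------------------------------------------

    def _validate(self) -> None:
        for ind in self._members.values():
            for role, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
                if pid is None:
                    continue
                if pid not in self._members:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.individual_id!r} not in pedigree")
                parent = self._members[pid]
                if parent.family_id != ind.family_id:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.individual_id!r} is in a different family")
                want = MALE if role == "father" else FEMALE
                if parent.sex != UNKNOWN and parent.sex != want:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.individual_id!r} has sex {parent.sex}")

    def _topological_order(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}  # 0 = visiting, 1 = done

        for start in self._members:
            if start in state:
                continue
            stack = [(start, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    state[node] = 1
                    order.append(node)
                    continue
                if state.get(node) == 1:
                    continue
                if state.get(node) == 0:
                    raise PedigreeError(f"pedigree contains a cycle through {node!r}")
                state[node] = 0
                stack.append((node, True))
                ind = self._members[node]
                for pid in (ind.father_id, ind.mother_id):
                    if pid is not None and state.get(pid) != 1:
                        stack.append((pid, False))
        return order


def kinship_matrix(ped: Pedigree) -> pd.DataFrame:
    """Kinship coefficients Φ for every pair, by the standard recursion.

    Founders are assumed non-inbred and mutually unrelated. For individual
    ``i`` with parents ``f, m``:

        Φ(i, i) = ½ (1 + Φ(f, m))
        Φ(i, j) = ½ (Φ(f, j) + Φ(m, j))        (j already placed, j ≠ i)

    with a missing parent contributing 0. Returned as a symmetric DataFrame
    indexed by individual id; cross-family entries are exactly 0.
    """
    order = ped.topological_order()
    n = len(order)
    pos = {iid: k for k, iid in enumerate(order)}
    phi = np.zeros((n, n))
    for iid in order:
        i = pos[iid]
        ind = ped[iid]
        fi = pos[ind.father_id] if ind.father_id else None
        mi = pos[ind.mother_id] if ind.mother_id else None
        if fi is None and mi is None:
            phi[i, i] = 0.5
        else:
            pf = phi[fi, :i] if fi is not None else 0.0
            pm = phi[mi, :i] if mi is not None else 0.0
            phi[i, :i] = 0.5 * (pf + pm)
            phi[:i, i] = phi[i, :i]
            fm = phi[fi, mi] if (fi is not None and mi is not None) else 0.0
            phi[i, i] = 0.5 * (1.0 + fm)
    # restore the pedigree's own id order
    out = pd.DataFrame(phi, index=order, columns=order)
    return out.loc[ped.ids, ped.ids]


def relationship_matrix(ped: Pedigree, ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Coefficient-of-relationship matrix R = 2Φ, ordered to ``ids``.

    Diagonal entries are ``1 + f`` (inbreeding coefficient ``f``), exactly 1
    for non-inbred individuals; cross-family entries are 0, so R is
    block-diagonal by family when ids are grouped by family.
    """
    phi = kinship_matrix(ped)
    if ids is None:
        ids = ped.ids
    missing = [i for i in ids if i not in phi.index]
    if missing:
        raise KeyError(f"ids not in pedigree: {missing}")
    return 2.0 * phi.loc[list(ids), list(ids)]


@dataclass
class CaseControlPairs:
    """Unordered pedigree-unrelated pairs split by case status."""

    caca: list[tuple[str, str]] = field(default_factory=list)
    caco: list[tuple[str, str]] = field(default_factory=list)
    coco: list[tuple[str, str]] = field(default_factory=list)

    def all_pairs(self) -> list[tuple[str, str]]:
        return self.caca + self.caco + self.coco


def unrelated_pairs(ped: Pedigree, case_status: Mapping[str, str]) -> CaseControlPairs:
    """All unordered kinship-0 pairs partitioned into CaCa / CaCo / CoCo.

    ``case_status`` maps individual id to ``"case"``, ``"control"`` or
    ``"missing"``; individuals with missing or absent status are excluded
    (logged). Pairs are sorted by id for determinism. Note that within-family
    pairs of married-in founders have kinship 0 and are included.
    """
    known = [i for i in ped.ids if case_status.get(i, "missing") in ("case", "control")]
    n_excluded = len(ped) - len(known)
    if n_excluded:
        logger.info("unrelated_pairs: excluding %d individuals with missing status", n_excluded)
    phi = kinship_matrix(ped).loc[known, known].to_numpy()
    is_case = np.array([case_status[i] == "case" for i in known])
    out = CaseControlPairs()
    order = sorted(range(len(known)), key=lambda k: known[k])
    for a_idx in range(len(order)):
        for b_idx in range(a_idx + 1, len(order)):
            i, j = order[a_idx], order[b_idx]
            if phi[i, j] != 0.0:
                continue
            pair = (known[i], known[j])
            n_cases = int(is_case[i]) + int(is_case[j])
            (out.caca if n_cases == 2 else out.caco if n_cases == 1 else out.coco).append(pair)
    return out
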
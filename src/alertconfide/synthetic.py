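"""Synthetic chemical inventories with planted coverage and label association.

Every screening statistic in this package can be exercised without external
data: the generator plants an exact number of alert-matching molecules
(deterministic coverage), diversifies them with verified structural variants,
and draws activity labels from two conditional probabilities —
P(active | hit) and P(active | no-hit) — with a seeded generator.

The default planted alert is a primary/secondary aliphatic alcohol pattern,
with a plain aromatic hydrocarbon as the guaranteed non-matching scaffold.
The generator makes no attempt to mimic real chemical-space distributions or
toxicokinetics; it provides ground truth for coverage and performance
arithmetic only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .errors import GenerationError
from .screening import InventoryRecord, StructuralAlert

DEFAULT_ALERT_PATTERN = "[CX4][OX2H]"
DEFAULT_HIT_SCAFFOLD = "CCO"        # ethanol: matches the aliphatic-alcohol pattern
DEFAULT_NOHIT_SCAFFOLD = "c1ccccc1"  # benzene: no sp3 carbinol, never matches


def _matches(smiles: str, pattern: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    query = Chem.MolFromSmarts(pattern)
    if mol is None:
        raise GenerationError(f"scaffold SMILES {smiles!r} does not parse")
    if query is None:
        raise GenerationError(f"alert pattern {pattern!r} does not parse")
    return mol.HasSubstructMatch(query)


@dataclass(frozen=True)
class SyntheticInventorySpec:
    """Recipe for a synthetic inventory with known ground truth.

    ``round(n * prevalence)`` molecules are built on the hit scaffold (all of
    them match ``alert_pattern`` by construction), the rest on the non-hit
    scaffold.  A molecule receives an activity label with probability
    ``label_fraction``; labelled molecules are active with probability
    ``p_active_given_hit`` or ``p_active_given_nohit`` according to their
    planted hit status.
    """

    n: int
    prevalence: float = 0.3
    p_active_given_hit: float = 0.8
    p_active_given_nohit: float = 0.1
    label_fraction: float = 1.0
    seed: int = 0
    alert_pattern: str = DEFAULT_ALERT_PATTERN
    hit_scaffold: str = DEFAULT_HIT_SCAFFOLD
    nohit_scaffold: str = DEFAULT_NOHIT_SCAFFOLD

    def __post_init__(self):
        if self.n < 1:
            raise GenerationError("n must be >= 1")
        for name in ("prevalence", "p_active_given_hit", "p_active_given_nohit", "label_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise GenerationError(f"{name} must be in [0, 1], got {value!r}")
        if not _matches(self.hit_scaffold, self.alert_pattern):
            raise GenerationError(
                f"hit scaffold {self.hit_scaffold!r} does not match "
                f"pattern {self.alert_pattern!r}"
            )
        if _matches(self.nohit_scaffold, self.alert_pattern):
            raise GenerationError(
                f"no-hit scaffold {self.nohit_scaffold!r} matches "
                f"pattern {self.alert_pattern!r}"
            )

    @property
    def n_hits(self) -> int:
        return round(self.n * self.prevalence)

    def planted_alert(self) -> StructuralAlert:
        return StructuralAlert(
            alert_id="planted",
            name="planted synthetic alert",
            patterns=(self.alert_pattern,),
            endpoint="synthetic activity",
        )


def structural_variants(
    scaffold: str,
    k: int,
    seed: int,
    pattern: str | None = None,
    max_attempts_per_variant: int = 50,
) -> list[str]:
    """Generate ``k`` distinct decorated versions of a scaffold.

    Each variant is built by attaching one to six methyl carbons at random
    positions with free valence, then verified to parse and (when *pattern*
    is given) to preserve the scaffold's match/no-match status against it.
    The same seed always yields the same list.
    """
    if k == 0:
        return []
    base = Chem.MolFromSmiles(scaffold)
    if base is None:
        raise GenerationError(f"scaffold SMILES {scaffold!r} does not parse")
    query = None
    base_status = None
    if pattern is not None:
        query = Chem.MolFromSmarts(pattern)
        if query is None:
            raise GenerationError(f"pattern {pattern!r} does not parse")
        base_status = base.HasSubstructMatch(query)
    rng = np.random.default_rng(seed)
    variants: list[str] = []
    seen = {Chem.MolToSmiles(base)}
    attempts_left = k * max_attempts_per_variant
    while len(variants) < k and attempts_left > 0:
        attempts_left -= 1
        mol = Chem.RWMol(Chem.MolFromSmiles(scaffold))
        n_additions = int(rng.integers(1, 7))
        ok = True
        for _ in range(n_additions):
            candidates = [
                atom.GetIdx()
                for atom in mol.GetAtoms()
                if atom.GetImplicitValence() > 0 and atom.GetAtomicNum() == 6
            ]
            if not candidates:
                ok = False
                break
            target = int(rng.choice(candidates))
            new_idx = mol.AddAtom(Chem.Atom(6))
            mol.AddBond(target, new_idx, Chem.BondType.SINGLE)
            mol.UpdatePropertyCache(strict=False)
        if not ok:
            continue
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        smiles = Chem.MolToSmiles(mol)
        if smiles in seen:
            continue
        if query is not None and mol.HasSubstructMatch(query) != base_status:
            continue
        seen.add(smiles)
        variants.append(smiles)
    if len(variants) < k:
        raise GenerationError(
            f"could only build {len(variants)} of {k} verified variants of "
            f"{scaffold!r} within the attempt budget"
        )
    return variants


def generate_inventory(spec: SyntheticInventorySpec) -> list[InventoryRecord]:
    """Build the inventory described by a spec.

    Exactly ``spec.n_hits`` molecules match the planted pattern; positions in
    the list are a seeded permutation, ids are ``mol_000001`` upwards in list
    order, and labels follow the spec's conditional probabilities.  Identical
    specs yield byte-identical inventories.
    """
    n_hits = spec.n_hits
    n_nohits = spec.n - n_hits
    rng = np.random.default_rng(spec.seed)

    # a small pool of verified variants per scaffold keeps matching non-trivial
    def build_pool(scaffold: str, count: int) -> list[str]:
        if count == 0:
            return []
        pool_size = min(max(count // 10, 1), 25)
        pool = [scaffold]
        if pool_size > 1:
            pool += structural_variants(
                scaffold, pool_size - 1, seed=int(rng.integers(0, 2**31)),
                pattern=spec.alert_pattern,
            )
        return pool

    hit_pool = build_pool(spec.hit_scaffold, n_hits)
    nohit_pool = build_pool(spec.nohit_scaffold, n_nohits)

    structures = [hit_pool[i % len(hit_pool)] for i in range(n_hits)]
    structures += [nohit_pool[i % len(nohit_pool)] for i in range(n_nohits)]
    is_hit = [True] * n_hits + [False] * n_nohits

    order = rng.permutation(spec.n)
    labelled = rng.random(spec.n) < spec.label_fraction
    active_draw = rng.random(spec.n)

    records = []
    for position, source_index in enumerate(order):
        smiles = structures[source_index]
        hit = is_hit[source_index]
        if labelled[position]:
            p_active = spec.p_active_given_hit if hit else spec.p_active_given_nohit
            activity = "active" if active_draw[position] < p_active else "inactive"
        else:
            activity = "unknown"
        records.append(
            InventoryRecord(
                molecule_id=f"mol_{position + 1:06d}",
                structure=smiles,
                activity=activity,
            )
        )
    return records
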
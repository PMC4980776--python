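"""Seeded synthetic molecules and properties.

Real training data for solubility- or logD-style endpoints lives in
external databases; every stage of this package is instead testable
against generated data.  Molecules are random connected heavy-atom graphs
(random spanning tree plus optional ring-closing edges, valence-legal
bond orders, a C/O/N element alphabet), not database samples — structural
diversity (branching, rings, heteroatoms) matters here, physical realism
does not.  The property generator then defines a continuous log-scale
endpoint as a sparse linear function of the molecules' signature counts
plus Gaussian noise, and returns the true coefficients so that estimation
experiments can measure recovery, not just fit.

Ground-truth coefficients default to height-1 signature counts: pooled
heights 1-3 are exactly collinear by refinement (a height-1 count is the
sum of its height-2 refinements), so individual coefficients on the
pooled dictionary are not identifiable by any regression.  The height-1
basis keeps the true model identifiable while the fitting side remains
free to use any height set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chemio import MolecularGraph, PropertyRecord, Qualifier, mol_to_graph
from .featurize import SignatureDictionary, build_dictionary, vectorize_multiset, vectors_to_csr
from .signatures import molecule_signatures

_VALENCE = {"C": 4, "N": 3, "O": 2}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic dataset.

    The defaults describe the standard study conditions used throughout
    the tests: 2000 drug-fragment-sized molecules, a carbon-rich C/O/N
    alphabet, about one ring per three molecules, a sparse true model
    over height-1 signature counts and 0.1 log-units of Gaussian noise.
    """

    n_molecules: int = 2000
    atom_range: tuple[int, int] = (4, 18)
    elements: tuple[str, ...] = ("C", "O", "N")
    element_probs: tuple[float, ...] = (0.8, 0.15, 0.05)
    ring_prob: float = 0.3
    double_bond_prob: float = 0.1
    heights: tuple[int, ...] = (1,)
    sparsity: float = 0.1
    noise_sigma: float = 0.1
    qualifier_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.element_probs) - 1.0) > 1e-9:
            raise ValueError("element probabilities must sum to 1")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.atom_range[0] < 1 or self.atom_range[0] > self.atom_range[1]:
            raise ValueError("invalid atom-count range")
        if any(e not in _VALENCE for e in self.elements):
            raise ValueError(f"elements must be drawn from {sorted(_VALENCE)}")


@dataclass
class GroundTruth:
    """The true sparse linear model behind a generated property."""

    dictionary: SignatureDictionary
    beta: np.ndarray
    bias: float
    heights: tuple[int, ...]
    noise_sigma: float


def _random_molecule(rng: np.random.Generator, spec: SyntheticSpec) -> Chem.Mol | None:
    n = int(rng.integers(spec.atom_range[0], spec.atom_range[1] + 1))
    symbols = list(rng.choice(spec.elements, size=n, p=spec.element_probs))
    free = [_VALENCE[s] for s in symbols]
    bonds: dict[tuple[int, int], int] = {}
    # random spanning tree: each new atom attaches to an earlier one with
    # free valence (always possible since every element has valence >= 2)
    for i in range(1, n):
        candidates = [j for j in range(i) if free[j] >= 1]
        j = int(candidates[rng.integers(len(candidates))])
        bonds[(j, i)] = 1
        free[i] -= 1
        free[j] -= 1
    # optional ring-closing edge between non-adjacent atoms with free valence
    if n >= 3 and rng.random() < spec.ring_prob:
        adjacent = set(bonds)
        pairs = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if free[i] >= 1 and free[j] >= 1 and (i, j) not in adjacent
        ]
        if pairs:
            i, j = pairs[rng.integers(len(pairs))]
            bonds[(i, j)] = 1
            free[i] -= 1
            free[j] -= 1
    # upgrade some bonds to double where both endpoints can afford it
    for (i, j) in list(bonds):
        if free[i] >= 1 and free[j] >= 1 and rng.random() < spec.double_bond_prob:
            bonds[(i, j)] = 2
            free[i] -= 1
            free[j] -= 1

    em = Chem.RWMol()
    for s in symbols:
        em.AddAtom(Chem.Atom(s))
    for (i, j), order in bonds.items():
        em.AddBond(i, j, Chem.BondType.SINGLE if order == 1 else Chem.BondType.DOUBLE)
    mol = em.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:  # pragma: no cover - valence bookkeeping should prevent this
        return None
    return mol


def generate_molecules(spec: SyntheticSpec) -> list[MolecularGraph]:
    """Generate the spec's random connected molecules, deterministically per seed."""
    rng = np.random.default_rng(spec.seed)
    graphs: list[MolecularGraph] = []
    retries = 0
    while len(graphs) < spec.n_molecules:
        mol = _random_molecule(rng, spec)
        if mol is None:
            retries += 1
            if retries > 100 * spec.n_molecules:
                raise RuntimeError("molecule generation failed too often; infeasible spec")
            continue
        graphs.append(mol_to_graph(mol, source=Chem.MolToSmiles(mol)))
    return graphs


def generate_property(
    molecules: Sequence[MolecularGraph],
    heights: Sequence[int] = (1,),
    sparsity: float = 0.1,
    noise_sigma: float = 0.1,
    seed: int = 0,
    *,
    qualifier_fraction: float = 0.0,
    min_prevalence: float = 0.05,
) -> tuple[list[PropertyRecord], GroundTruth]:
    """Define a sparse linear property over signature counts.

    Builds the signature dictionary of the supplied molecules, draws a
    sparse coefficient vector beta with exactly ``ceil(sparsity * N)``
    non-zeros (placed on features present in at least ``min_prevalence``
    of the molecules, so the signal is estimable) and a bias, and sets

        y = beta . counts + bias + N(0, sigma^2).

    With ``qualifier_fraction`` > 0 that fraction of records is marked
    with a ">" qualifier, for exercising the inequality filter.
    """
    if noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    rng = np.random.default_rng(seed)
    multisets = [molecule_signatures(g, heights) for g in molecules]
    dictionary = build_dictionary(multisets)
    X = vectors_to_csr([vectorize_multiset(ms, dictionary) for ms in multisets], len(dictionary))

    n, p = X.shape
    n_nonzero = math.ceil(sparsity * p)
    prevalence = np.asarray((X > 0).sum(axis=0)).ravel() / n
    eligible = np.flatnonzero(prevalence >= min_prevalence)
    if eligible.size < n_nonzero:
        eligible = np.argsort(prevalence)[::-1][:n_nonzero]
    support = rng.choice(eligible, size=n_nonzero, replace=False)
    beta = np.zeros(p)
    beta[support] = rng.uniform(0.25, 1.0, size=n_nonzero) * rng.choice([-1.0, 1.0], size=n_nonzero)
    bias = float(rng.uniform(-1.0, 1.0))

    y = np.asarray(X @ beta).ravel() + bias + rng.normal(0.0, noise_sigma, size=n)
    qualifiers = np.full(n, False)
    if qualifier_fraction > 0:
        k = int(round(qualifier_fraction * n))
        qualifiers[rng.choice(n, size=k, replace=False)] = True

    records = [
        PropertyRecord(
            molecule=g,
            value=float(y[i]),
            qualifier=Qualifier.GREATER if qualifiers[i] else Qualifier.EXACT,
            identifier=f"synth-{i:05d}",
        )
        for i, g in enumerate(molecules)
    ]
    truth = GroundTruth(
        dictionary=dictionary,
        beta=beta,
        bias=bias,
        heights=tuple(int(h) for h in heights),
        noise_sigma=noise_sigma,
    )
    return records, truth


def make_dataset(spec: SyntheticSpec) -> tuple[list[PropertyRecord], GroundTruth]:
    """Generate molecules and their property under one spec/seed."""
    molecules = generate_molecules(spec)
    return generate_property(
        molecules,
        heights=spec.heights,
        sparsity=spec.sparsity,
        noise_sigma=spec.noise_sigma,
        seed=spec.seed,
        qualifier_fraction=spec.qualifier_fraction,
    )


def write_csv(records: Sequence[PropertyRecord], path) -> None:
    """Write records as a CSV in the dialect the loader reads.

    Column order and float formatting are fixed, so the same seed gives a
    byte-identical file.
    """
    with open(path, "w") as fh:
        fh.write("id,smiles,qualifier,value\n")
        for r in records:
            smiles = r.molecule.source or r.molecule.to_smiles()
            fh.write(f"{r.identifier},{smiles},{r.qualifier.value},{r.value!r}\n")
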
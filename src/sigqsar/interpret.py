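"""Per-atom interpretation of linear signature models.

A linear model's prediction is a sum of signature weights, and every
signature has a root atom, so the prediction decomposes exactly over
atoms: each surviving (root, text) signature occurrence credits its
weight to the root atom.  The per-atom raw scores therefore satisfy

    sum_atoms raw(atom) + bias == prediction

which makes the colouring an exact accounting of the model output rather
than a heuristic saliency.  Normalized scores (raw / max |raw|, in
[-1, 1]) drive red/blue style highlighting; the single most-contributing
signature is also reported, together with its atom set (the height-h ball
around its root).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chemio import MolecularGraph
from .featurize import SignatureDictionary
from .signatures import atom_signature, ball_atoms
from .svr import SvrModel


@dataclass
class TopSignature:
    """The signature occurrence with the largest absolute contribution."""

    text: str
    root: int
    height: int
    contribution: float

    def atom_set(self, graph: MolecularGraph) -> set[int]:
        return ball_atoms(graph, self.root, self.height)


@dataclass
class AtomContributionMap:
    """Exact per-atom decomposition of one prediction."""

    raw: np.ndarray
    normalized: np.ndarray
    top: TopSignature | None
    prediction: float
    bias: float


def atom_contributions(
    model: SvrModel,
    dictionary: SignatureDictionary,
    graph: MolecularGraph,
    heights: Sequence[int] = (1, 2, 3),
) -> AtomContributionMap:
    """Decompose a prediction into per-atom contributions.

    Each atom's raw score is the sum of the model weights of the
    signatures rooted at it (per root, identical texts from different
    heights count once, mirroring featurization); signatures unknown to
    the dictionary contribute nothing.  Ties for the top signature go to
    the lower atom index, then the shorter text.
    """
    if model.n_features != len(dictionary):
        raise ValueError(
            f"model has {model.n_features} weights but dictionary has {len(dictionary)} entries"
        )
    index = dictionary.index
    raw = np.zeros(graph.n_atoms)
    top: TopSignature | None = None
    heights = sorted(set(int(h) for h in heights))
    for root in range(graph.n_atoms):
        seen: dict[str, int] = {}
        for h in heights:
            text = atom_signature(graph, root, h).text
            if text not in seen:
                seen[text] = h
        for text, h in seen.items():
            i = index.get(text)
            if i is None:
                continue
            weight = float(model.weights[i - 1])
            raw[root] += weight
            if weight != 0.0 and (
                top is None
                or abs(weight) > abs(top.contribution)
                or (
                    abs(weight) == abs(top.contribution)
                    and (root, len(text)) < (top.root, len(top.text))
                )
            ):
                top = TopSignature(text=text, root=root, height=h, contribution=weight)

    max_abs = float(np.max(np.abs(raw))) if raw.size else 0.0
    normalized = raw / max_abs if max_abs > 0 else np.zeros_like(raw)
    prediction = float(raw.sum() + model.bias)
    return AtomContributionMap(
        raw=raw, normalized=normalized, top=top, prediction=prediction, bias=model.bias
    )


def export_annotations(cmap: AtomContributionMap, graph: MolecularGraph, out_dir) -> dict:
    """Write the annotated structure (SDF) and a per-atom TSV.

    The SDF carries the per-atom raw scores as a newline-separated
    property block (``atom_scores``), the prediction, and the atom-index
    list of the top signature; the TSV lists (index, element, raw,
    normalized) per atom.  Returns the paths written.
    """
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    sdf_path = os.path.join(out_dir, "annotated.sdf")
    tsv_path = os.path.join(out_dir, "atom_scores.tsv")

    mol = graph.to_rdkit()
    mol.SetProp("atom_scores", "\n".join(repr(float(x)) for x in cmap.raw))
    mol.SetProp("prediction", repr(cmap.prediction))
    if cmap.top is not None:
        atoms = sorted(cmap.top.atom_set(graph))
        mol.SetProp("top_signature", cmap.top.text)
        mol.SetProp("top_signature_atoms", " ".join(str(a) for a in atoms))
    writer = Chem.SDWriter(sdf_path)
    writer.write(mol)
    writer.close()

    pd.DataFrame(
        {
            "atom": range(graph.n_atoms),
            "element": [a.symbol for a in graph.atoms],
            "raw": cmap.raw,
            "normalized": cmap.normalized,
        }
    ).to_csv(tsv_path, sep="\t", index=False)
    return {"sdf": sdf_path, "tsv": tsv_path}
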
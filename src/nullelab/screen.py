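"""Similarity mapping of generated structures onto a purchasable library,
followed by a QSAR potency filter.

Generated molecules are rarely purchasable; the screen maps each one onto
the closest catalog entries by Tanimoto similarity of ECFP4 fingerprints
(2048 bits, radius 2) at an inclusive threshold (default 0.40), then keeps
library molecules whose QSAR-predicted normalized aggregation half-time
clears a potency cutoff (default 1.5, echoing the 50%-increase potency
notion behind the KIC50).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import MoleculeState, canonicalize, fingerprint, tanimoto
from .qsar import TrainedQsarModel

DEFAULT_THRESHOLD = 0.40
DEFAULT_POTENCY_CUTOFF = 1.5


@dataclass(frozen=True)
class SimilarityHit:
    """One (query, library) pair at or above the similarity threshold."""

    query_id: str
    query_smiles: str
    library_id: str
    library_smiles: str
    tanimoto: float
    best_for_query: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.tanimoto <= 1.0:
            raise ValueError("tanimoto must lie in [0, 1]")


@dataclass
class ScreenResult:
    """Similarity hits, per-hit QSAR predictions, and the retained subset."""

    hits: list[SimilarityHit]
    predictions: dict[str, float]        # library_id -> predicted value
    retained: list[SimilarityHit]
    cutoff: float

    def __post_init__(self) -> None:
        hit_keys = {(h.query_id, h.library_id) for h in self.hits}
        if not {(h.query_id, h.library_id) for h in self.retained} <= hit_keys:
            raise ValueError("retained must be a subset of hits")

    def to_frame(self):
        import pandas as pd

        retained_keys = {(h.query_id, h.library_id) for h in self.retained}
        rows = [
            {
                "query": h.query_id,
                "query_smiles": h.query_smiles,
                "library_id": h.library_id,
                "library_smiles": h.library_smiles,
                "tanimoto": h.tanimoto,
                "prediction": self.predictions.get(h.library_id, np.nan),
                "retained": (h.query_id, h.library_id) in retained_keys,
            }
            for h in self.hits
        ]
        return pd.DataFrame(rows)


def _normalize_records(
    items: Sequence[MoleculeState | str | tuple[str, str]], prefix: str
) -> list[tuple[str, str]]:
    """Coerce molecules to (canonical_smiles, identifier) pairs."""
    records = []
    for i, item in enumerate(items):
        if isinstance(item, tuple):
            smi, ident = item
            records.append((canonicalize(smi), ident))
        elif isinstance(item, MoleculeState):
            records.append((item.structure, f"{prefix}{i}"))
        else:
            records.append((canonicalize(item), f"{prefix}{i}"))
    return records


def similarity_search(
    queries: Sequence[MoleculeState | str | tuple[str, str]],
    library: Sequence[MoleculeState | str | tuple[str, str]],
    threshold: float = DEFAULT_THRESHOLD,
    radius: int = 2,
    n_bits: int = 2048,
) -> list[SimilarityHit]:
    """All (query, library) pairs with Tanimoto >= threshold, most similar first.

    Duplicate library entries are collapsed by canonical structure (first
    identifier wins); ties at the threshold boundary are retained
    (inclusive comparison).  Each query's single best hit is flagged.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    query_recs = _normalize_records(queries, "query")
    lib_recs = _normalize_records(library, "lib")
    if not lib_recs:
        warnings.warn("similarity_search: empty library, returning no hits")
        return []
    seen: dict[str, str] = {}
    for smi, ident in lib_recs:
        seen.setdefault(smi, ident)
    lib_unique = [(smi, ident) for smi, ident in seen.items()]

    lib_fps = [fingerprint(smi, radius, n_bits) for smi, _ in lib_unique]
    hits: list[SimilarityHit] = []
    for q_smi, q_id in query_recs:
        q_fp = fingerprint(q_smi, radius, n_bits)
        sims = [tanimoto(q_fp, lf) for lf in lib_fps]
        best_idx = int(np.argmax(sims)) if sims else -1
        for j, sim in enumerate(sims):
            if sim >= threshold:
                l_smi, l_id = lib_unique[j]
                hits.append(
                    SimilarityHit(
                        query_id=q_id,
                        query_smiles=q_smi,
                        library_id=l_id,
                        library_smiles=l_smi,
                        tanimoto=float(sim),
                        best_for_query=(j == best_idx),
                    )
                )
    hits.sort(key=lambda h: (-h.tanimoto, h.query_id, h.library_id))
    return hits


def potency_filter(
    hits: Sequence[SimilarityHit],
    model: TrainedQsarModel,
    cutoff: float = DEFAULT_POTENCY_CUTOFF,
) -> ScreenResult:
    """Retain hit library molecules predicted at least as potent as ``cutoff``.

    The model endpoint must be the normalized aggregation half-time;
    predictions for every hit are reported, retained or not.
    """
    if model.endpoint != "normalized_half_time":
        raise ValueError(
            f"potency_filter requires a normalized_half_time model, got {model.endpoint!r}"
        )
    hits = list(hits)
    unique: dict[str, str] = {}
    for h in hits:
        unique.setdefault(h.library_id, h.library_smiles)
    lib_ids = list(unique)
    preds = (
        model.predict([unique[i] for i in lib_ids]) if lib_ids else np.empty(0)
    )
    predictions = {i: float(p) for i, p in zip(lib_ids, preds)}
    retained = [h for h in hits if predictions[h.library_id] >= cutoff]
    return ScreenResult(hits=hits, predictions=predictions, retained=retained, cutoff=cutoff)
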
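"""Hit calling, similarity clustering and diversified hit selection.

Primary-screen hits are compounds whose normalized relative inhibition
meets a threshold (50% by default).  Hits are clustered by building a
graph whose edges connect compounds with Tanimoto similarity of their
Morgan (ECFP4-like, radius 2) fingerprints above an edge threshold and
running Louvain community detection on it.  Each cluster is summarised
by a scaffold — the maximum common substructure of its members — and a
diversified subset is picked per cluster by a ligand-efficiency proxy
(normalized inhibition divided by molecular weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFMCS, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

from .dose_response import classify_activity

UNLABELED = "unlabeled"


class FingerprintError(ValueError):
    """Unparseable structure or mismatched fingerprint lengths."""


@dataclass(frozen=True)
class CompoundRecord:
    """One library entry: structure, weight and (once screened) activity."""

    compound_id: str
    smiles: str
    mw: float
    n_undefined_stereocenters: int = 0
    k_norm: float | None = None


@dataclass
class ClusterSet:
    """Louvain communities over the hit similarity graph.

    ``clusters`` maps a cluster id to the sorted member compound ids;
    the members form an exact partition of the clustered hit set.
    """

    clusters: dict[int, list[str]]
    scaffolds: dict[int, str] = field(default_factory=dict)
    labels: dict[int, str] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_singletons(self) -> int:
        return sum(1 for m in self.clusters.values() if len(m) == 1)

    def membership(self) -> dict[str, int]:
        return {cid: k for k, members in self.clusters.items() for cid in members}


# ---------------------------------------------------------------------------
# Structures and fingerprints


def canonical_smiles(smiles: str) -> str:
    """Salt-stripped canonical SMILES (largest organic fragment kept)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FingerprintError(f"unparseable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return Chem.MolToSmiles(mol)


def morgan_fingerprints(
    smiles: list[str] | pd.Series, radius: int = 2, n_bits: int = 2048
) -> np.ndarray:
    """Binary Morgan fingerprints, one row per structure (salts stripped)."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = np.zeros((len(smiles), n_bits), dtype=np.uint8)
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(canonical_smiles(smi))
        fp = gen.GetFingerprint(mol)
        out[i, list(fp.GetOnBits())] = 1
    return out


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto similarity |a & b| / |a | b| of two binary fingerprints.

    Two all-zero fingerprints are defined as identical (similarity 1.0).
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise FingerprintError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_matrix(fps_a: np.ndarray, fps_b: np.ndarray | None = None) -> np.ndarray:
    """All-pairs Tanimoto similarities between two fingerprint stacks."""
    a = np.asarray(fps_a, dtype=np.float64)
    b = a if fps_b is None else np.asarray(fps_b, dtype=np.float64)
    inter = a @ b.T
    counts_a = a.sum(axis=1, keepdims=True)
    counts_b = b.sum(axis=1, keepdims=True)
    union = counts_a + counts_b.T - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


# ---------------------------------------------------------------------------
# Hit calling and clustering


def call_hits(records: pd.DataFrame, threshold: float = 50.0) -> set[str]:
    """Compound ids with k_norm >= threshold (boundary inclusive)."""
    if records["k_norm"].isna().any():
        raise ValueError("k_norm missing for some records; normalize first")
    mask = records["k_norm"] >= threshold
    return set(records.loc[mask, "compound_id"].astype(str))


def build_similarity_graph(
    ids: list[str], fps: np.ndarray, edge_threshold: float = 0.4
) -> nx.Graph:
    """Undirected graph: edge (i, j) iff TS(i, j) >= edge_threshold, weight TS."""
    if len(ids) != len(fps):
        raise FingerprintError("ids and fingerprints differ in length")
    g = nx.Graph()
    g.add_nodes_from(ids)
    sim = tanimoto_matrix(fps)
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    keep = sim[iu, ju] >= edge_threshold
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(ids[i], ids[j], weight=float(sim[i, j]))
    return g


def louvain_cluster(graph: nx.Graph, seed: int = 0) -> ClusterSet:
    """Louvain communities (modularity-maximizing, seeded) over the graph.

    Isolated nodes come out as singletons.  Cluster ids are assigned in
    order of each cluster's lexicographically smallest member so the
    labelling is deterministic.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    comms = nx.community.louvain_communities(graph, weight="weight", seed=seed)
    ordered = sorted((sorted(str(m) for m in c) for c in comms), key=lambda c: c[0])
    return ClusterSet(clusters={k: members for k, members in enumerate(ordered)})


# ---------------------------------------------------------------------------
# Scaffolds


def mcs_scaffold(
    smiles: list[str], timeout_s: int = 10, min_atoms: int = 3
) -> str:
    """Maximum-common-substructure scaffold of a cluster's members.

    Singletons get their Bemis-Murcko-style framework.  If the MCS falls
    below ``min_atoms`` heavy atoms (or the search finds nothing), the
    scaffold is reported empty; the cluster itself is retained by callers.
    The MCS search is bounded by ``timeout_s`` with best-so-far returned.
    """
    if not smiles:
        raise ValueError("need at least one structure")
    mols = [Chem.MolFromSmiles(s) for s in smiles]
    if any(m is None for m in mols):
        bad = [s for s, m in zip(smiles, mols) if m is None]
        raise FingerprintError(f"unparseable SMILES: {bad[:3]}")
    if len(mols) == 1:
        core = MurckoScaffold.GetScaffoldForMol(mols[0])
        if core.GetNumHeavyAtoms() >= min_atoms:
            return Chem.MolToSmiles(core)
        return Chem.MolToSmiles(mols[0])  # acyclic: framework is the molecule
    res = rdFMCS.FindMCS(
        mols,
        timeout=timeout_s,
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrder,
        ringMatchesRingOnly=True,
    )
    if res.numAtoms < min_atoms or not res.smartsString:
        return ""
    return res.smartsString


def attach_scaffolds(
    clusters: ClusterSet, records: pd.DataFrame, timeout_s: int = 10, min_atoms: int = 3
) -> ClusterSet:
    """Compute and store the MCS scaffold of every cluster."""
    smiles_of = dict(zip(records["compound_id"].astype(str), records["smiles"]))
    for k, members in clusters.clusters.items():
        clusters.scaffolds[k] = mcs_scaffold(
            [smiles_of[m] for m in members], timeout_s=timeout_s, min_atoms=min_atoms
        )
    return clusters


# ---------------------------------------------------------------------------
# Diversified selection and labelling


def ligand_efficiency_proxy(k_norm: float, mw: float) -> float:
    """Activity per unit molecular weight: k_norm / mw (percent*mol/g)."""
    if mw <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw}")
    return k_norm / mw


def diversify(
    clusters: ClusterSet, records: pd.DataFrame, k_per_cluster: int = 5
) -> pd.DataFrame:
    """Top-``k_per_cluster`` members of each cluster by the LE proxy.

    Ties are broken by compound id (lexicographic).  Returns one row per
    cluster member with columns compound_id, cluster_id, le_proxy and
    selected flag; the selected rows form the diversified hit set.
    """
    recs = records.set_index(records["compound_id"].astype(str))
    rows = []
    for cid, members in clusters.clusters.items():
        scored = []
        for m in members:
            r = recs.loc[m]
            scored.append((m, ligand_efficiency_proxy(float(r["k_norm"]), float(r["mw"]))))
        scored.sort(key=lambda t: (-t[1], t[0]))
        chosen = {m for m, _ in scored[: min(k_per_cluster, len(scored))]}
        for m, le in scored:
            rows.append(
                {
                    "compound_id": m,
                    "cluster_id": cid,
                    "le_proxy": le,
                    "selected": m in chosen,
                }
            )
    return pd.DataFrame(rows)


def label_scaffolds(clusters: ClusterSet, pic50_by_compound: dict[str, float]) -> ClusterSet:
    """Label each cluster by the activity class of its most potent member.

    Clusters with no assayed member stay ``unlabeled``.
    """
    for k, members in clusters.clusters.items():
        vals = [pic50_by_compound[m] for m in members if m in pic50_by_compound]
        clusters.labels[k] = classify_activity(max(vals)) if vals else UNLABELED
    return clusters


# ---------------------------------------------------------------------------
# Novelty against a reference set


def novelty_counts(
    hit_ids: list[str],
    hit_fps: np.ndarray,
    reference_fps: np.ndarray,
    thresholds: list[float],
    clusters: ClusterSet | None = None,
) -> pd.DataFrame:
    """Hits (and their scaffolds) with a reference neighbor above each threshold.

    For each threshold t the count is of hits whose nearest reference
    neighbor has TS strictly greater than t; scaffold counts are of
    distinct clusters containing at least one such hit.  An empty
    reference set yields zero counts everywhere.
    """
    if len(reference_fps) == 0:
        nearest = np.zeros(len(hit_ids))
    else:
        nearest = tanimoto_matrix(hit_fps, reference_fps).max(axis=1)
    member_of = clusters.membership() if clusters is not None else None
    rows = []
    for t in thresholds:
        mask = nearest > t
        n_hits = int(mask.sum())
        if member_of is not None:
            scaffs = {member_of[h] for h, m in zip(hit_ids, mask) if m and h in member_of}
            n_scaff = len(scaffs)
        else:
            n_scaff = None
        rows.append({"threshold": t, "hits": n_hits, "scaffolds": n_scaff})
    return pd.DataFrame(rows)


def library_records(library: pd.DataFrame) -> list[CompoundRecord]:
    """View a library table as CompoundRecord objects."""
    return [
        CompoundRecord(
            compound_id=str(r.compound_id),
            smiles=r.smiles,
            mw=float(r.mw),
            n_undefined_stereocenters=int(getattr(r, "n_undefined_stereocenters", 0)),
            k_norm=float(r.k_norm) if hasattr(r, "k_norm") and pd.notna(r.k_norm) else None,
        )
        for r in library.itertuples()
    ]


def undefined_stereocenters(smiles: str) -> int:
    """Count of potential stereocenters with unspecified configuration."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FingerprintError(f"unparseable SMILES: {smiles!r}")
    return int(rdMolDescriptors.CalcNumUnspecifiedAtomStereoCenters(mol))


def molecular_weight(smiles: str) -> float:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FingerprintError(f"unparseable SMILES: {smiles!r}")
    return float(Descriptors.MolWt(mol))
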
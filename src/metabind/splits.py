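"""Leakage-controlled benchmark splitting.

Proteins are grouped into sequence-identity clusters (a greedy longest-first
stand-in for cd-hit at 40% identity; externally computed cluster maps are
accepted verbatim) and molecules into Bemis-Murcko scaffold groups.  The
interaction records are then partitioned into:

* **train** — 95% of the proteins from data-rich ("train") clusters, paired
  with molecules whose scaffold is in the 95% train scaffold set;
* **transductive** — the held-out 5% of train-cluster proteins with train
  scaffolds: every cluster and scaffold is seen, no pair is;
* **inductive** — proteins from data-poor ("test") clusters with held-out
  scaffolds: neither cluster nor scaffold is seen;
* **semi-inductive** — everything else (the operational "rest" rule).

Clusters containing any protein with fewer than 20 associated molecules are
routed to the test side, since meta-learning needs data-rich training tasks.

Few-shot sets take, per protein of the combined semi-inductive + inductive
pool, exactly 5 binding and 5 nonbinding records for fine-tuning and leave
the rest for testing; proteins lacking either are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import BINDING, NONBINDING, InteractionRecord


@dataclass
class SplitBundle:
    train: list = field(default_factory=list)
    transductive: list = field(default_factory=list)
    semi_inductive: list = field(default_factory=list)
    inductive: list = field(default_factory=list)
    fewshot_finetune: dict = field(default_factory=dict)
    fewshot_test: dict = field(default_factory=dict)
    cluster_of: dict = field(default_factory=dict)
    scaffold_of: dict = field(default_factory=dict)

    @property
    def partitions(self) -> dict[str, list]:
        return {"train": self.train, "transductive": self.transductive,
                "semi_inductive": self.semi_inductive,
                "inductive": self.inductive}


# ---------------------------------------------------------------------------
# protein clustering
# ---------------------------------------------------------------------------

def sequence_identity(a: str, b: str) -> float:
    """Matched positions of the global alignment divided by the longer length.

    Scored with match=1, mismatch=0 and zero gap penalties, the optimal global
    alignment score equals the longest-common-subsequence length, which is the
    matched-position count used here.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    return aligner.score(a, b) / max(len(a), len(b))


def cluster_proteins(sequences: dict[str, str],
                     identity_threshold: float = 0.4) -> dict[str, str]:
    """Greedy longest-first clustering (cd-hit style stand-in).

    Sequences are sorted by decreasing length (ties by id); each joins the
    first cluster whose representative is at least ``identity_threshold``
    identical, else founds a new cluster named after its representative.
    """
    if not sequences:
        raise ValueError("no sequences")
    if not 0 < identity_threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    for pid, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence for {pid!r}")
    order = sorted(sequences, key=lambda p: (-len(sequences[p]), p))
    reps: list[str] = []
    assignment: dict[str, str] = {}
    for pid in order:
        for rep in reps:
            if sequence_identity(sequences[pid], sequences[rep]) >= identity_threshold:
                assignment[pid] = rep
                break
        else:
            reps.append(pid)
            assignment[pid] = pid
    return assignment


# ---------------------------------------------------------------------------
# molecule scaffolds
# ---------------------------------------------------------------------------

def scaffold_key(smiles: str) -> str:
    """Canonical Bemis-Murcko scaffold SMILES; '' for acyclic molecules."""
    from rdkit import Chem
    from rdkit.Chem.Scaffolds import MurckoScaffold

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


# ---------------------------------------------------------------------------
# the main partition
# ---------------------------------------------------------------------------

def make_splits(records: list[InteractionRecord],
                cluster_of: dict[str, str],
                scaffold_of: dict[str, str],
                train_protein_ratio: float = 0.95,
                train_scaffold_ratio: float = 0.95,
                min_molecules: int = 20,
                seed: int = 0,
                strict_semi_inductive: bool = False) -> SplitBundle:
    """Partition records into train / transductive / semi-inductive / inductive.

    With ``strict_semi_inductive`` the semi-inductive bucket is additionally
    filtered to the definitional case (seen cluster, unseen scaffold); by
    default it is the operational "rest" bucket.
    """
    if not 0 < train_protein_ratio < 1 or not 0 < train_scaffold_ratio < 1:
        raise ValueError("ratios must be in (0, 1)")
    for r in records:
        if r.protein_id not in cluster_of:
            raise KeyError(f"no cluster for protein {r.protein_id!r}")
        if r.molecule_id not in scaffold_of:
            raise KeyError(f"no scaffold for molecule {r.molecule_id!r}")

    rng = np.random.default_rng(seed)

    # canonical order first so the partition is invariant to record order
    records = sorted(records, key=lambda r: (r.protein_id, r.molecule_id,
                                             r.label, r.provenance))

    # (i) scaffold split
    scaffolds = sorted({scaffold_of[r.molecule_id] for r in records})
    perm = rng.permutation(len(scaffolds))
    n_train_sc = int(round(train_scaffold_ratio * len(scaffolds)))
    train_scaffolds = {scaffolds[i] for i in perm[:n_train_sc]}

    # (ii) cluster routing by data richness
    mols_per_protein: dict[str, set] = {}
    for r in records:
        mols_per_protein.setdefault(r.protein_id, set()).add(r.molecule_id)
    proteins = sorted(mols_per_protein)
    clusters = sorted({cluster_of[p] for p in proteins})
    test_clusters = {cluster_of[p] for p in proteins
                     if len(mols_per_protein[p]) < min_molecules}
    train_clusters = [c for c in clusters if c not in test_clusters]

    # (iii) 95/5 protein split within train clusters
    tc_proteins = sorted(p for p in proteins if cluster_of[p] in train_clusters)
    perm = rng.permutation(len(tc_proteins))
    n_hold = len(tc_proteins) - int(round(train_protein_ratio * len(tc_proteins)))
    cluster_size: dict[str, int] = {}
    for p in tc_proteins:
        cluster_size[cluster_of[p]] = cluster_size.get(cluster_of[p], 0) + 1
    # hold out proteins only from clusters that keep >=1 train member, so the
    # transductive set never contains an unseen cluster
    transductive_proteins: set[str] = set()
    remaining = dict(cluster_size)
    for i in perm:
        if len(transductive_proteins) >= n_hold:
            break
        p = tc_proteins[i]
        if remaining[cluster_of[p]] >= 2:
            transductive_proteins.add(p)
            remaining[cluster_of[p]] -= 1
    train_proteins = {p for p in tc_proteins if p not in transductive_proteins}

    bundle = SplitBundle(cluster_of=dict(cluster_of), scaffold_of=dict(scaffold_of))
    for r in records:
        sc_train = scaffold_of[r.molecule_id] in train_scaffolds
        in_test_cluster = cluster_of[r.protein_id] in test_clusters
        if r.protein_id in train_proteins and sc_train:
            bundle.train.append(r)
        elif r.protein_id in transductive_proteins and sc_train:
            bundle.transductive.append(r)
        elif in_test_cluster and not sc_train:
            bundle.inductive.append(r)
        else:
            if strict_semi_inductive and (in_test_cluster or sc_train):
                continue    # definitional filter: seen cluster, unseen scaffold
            bundle.semi_inductive.append(r)
    return bundle


def make_fewshot(semi_inductive: list[InteractionRecord],
                 inductive: list[InteractionRecord],
                 k_pos: int = 5, k_neg: int = 5,
                 seed: int = 0) -> tuple[dict, dict]:
    """Per-protein 5+5 fine-tune sets from the combined held-out pools.

    Proteins with fewer than ``k_pos`` binding or ``k_neg`` nonbinding records
    are excluded from both outputs.
    """
    by_protein: dict[str, list] = {}
    for r in sorted(semi_inductive + inductive,
                    key=lambda r: (r.protein_id, r.molecule_id, r.label)):
        by_protein.setdefault(r.protein_id, []).append(r)

    rng = np.random.default_rng(seed)
    finetune: dict[str, list] = {}
    test: dict[str, list] = {}
    for pid in sorted(by_protein):
        recs = by_protein[pid]
        pos = [r for r in recs if r.label == BINDING]
        neg = [r for r in recs if r.label == NONBINDING]
        if len(pos) < k_pos or len(neg) < k_neg:
            continue
        pos_idx = rng.choice(len(pos), size=k_pos, replace=False)
        neg_idx = rng.choice(len(neg), size=k_neg, replace=False)
        ft = [pos[i] for i in sorted(pos_idx)] + [neg[i] for i in sorted(neg_idx)]
        ft_set = set(id(r) for r in ft)
        finetune[pid] = ft
        test[pid] = [r for r in recs if id(r) not in ft_set]
    return finetune, test


# ---------------------------------------------------------------------------
# invariant checking (used by tests and by callers wanting a guarantee)
# ---------------------------------------------------------------------------

def check_bundle(bundle: SplitBundle) -> list[str]:
    """Return a list of violated invariants (empty = all good)."""
    problems = []
    parts = bundle.partitions
    seen_pairs: dict[tuple, str] = {}
    for name, recs in parts.items():
        for r in recs:
            if r.pair in seen_pairs and seen_pairs[r.pair] != name:
                problems.append(f"pair {r.pair} in both {seen_pairs[r.pair]} and {name}")
            seen_pairs.setdefault(r.pair, name)

    train_clusters = {bundle.cluster_of[r.protein_id] for r in bundle.train}
    train_scaffolds = {bundle.scaffold_of[r.molecule_id] for r in bundle.train}
    for r in bundle.inductive:
        if bundle.cluster_of[r.protein_id] in train_clusters:
            problems.append(f"inductive protein {r.protein_id} shares a train cluster")
        if bundle.scaffold_of[r.molecule_id] in train_scaffolds:
            problems.append(f"inductive molecule {r.molecule_id} shares a train scaffold")
    for r in bundle.transductive:
        if bundle.train and bundle.cluster_of[r.protein_id] not in train_clusters:
            problems.append(f"transductive protein {r.protein_id} cluster unseen")
        if bundle.train and bundle.scaffold_of[r.molecule_id] not in train_scaffolds:
            problems.append(f"transductive molecule {r.molecule_id} scaffold unseen")

    for pid, ft in bundle.fewshot_finetune.items():
        n_pos = sum(r.label == BINDING for r in ft)
        n_neg = sum(r.label == NONBINDING for r in ft)
        if (n_pos, n_neg) != (5, 5):
            problems.append(f"fewshot finetune for {pid} is {n_pos}+{n_neg}")
        overlap = {r.pair for r in ft} & {r.pair for r in bundle.fewshot_test.get(pid, [])}
        if overlap:
            problems.append(f"fewshot overlap for {pid}: {overlap}")
    return problems
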
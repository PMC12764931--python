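"""Heterogeneous drug/protein/pathway knowledge graph: containers and ingestion.

The graph couples three node types through four undirected relations --
drug-target, drug-drug, drug-pathway and pathway-target.  Nodes of one type
occupy a contiguous 0-based id block ordered drug < protein < pathway so the
spectral bases computed downstream are reproducible.  Drug-target edges carry
action tokens (inhibitor/agonist/...), drug-drug edges carry free-text
interaction descriptions that the safety-penalty parser consumes verbatim.

Two ingestion paths produce identical graphs on equivalent content: a
DrugBank-dialect XML subset and simplified TSV tables (the dialect the
synthetic generator writes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from lxml import etree

logger = logging.getLogger(__name__)

RELATIONS = ("drug_target", "drug_drug", "drug_pathway", "pathway_target")
NODE_TYPES = ("drug", "protein", "pathway")

#: admissible (source type, target type) per relation
RELATION_SCHEMA = {
    "drug_target": ("drug", "protein"),
    "drug_drug": ("drug", "drug"),
    "drug_pathway": ("drug", "pathway"),
    "pathway_target": ("pathway", "protein"),
}

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class GraphSchemaError(ValueError):
    """Raised when nodes/edges violate the typed relation schema."""


class RecordValidationError(ValueError):
    """Raised when an ingested record is missing required fields."""


class XMLParseError(ValueError):
    """Raised for malformed XML, with the offending line when known."""


# --------------------------------------------------------------------------- types
@dataclass
class HeteroGraph:
    """Typed node/edge store with per-relation adjacency and node features."""

    node_type: np.ndarray  # int codes indexing NODE_TYPES
    records: list  # one dict per node
    edges: dict  # relation -> (E, 2) int array, undirected
    edge_attrs: dict = field(default_factory=dict)  # relation -> list aligned with edges
    X: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_type)

    def nodes_of_type(self, node_type: str) -> np.ndarray:
        return np.flatnonzero(self.node_type == NODE_TYPES.index(node_type))

    def adjacency(self, relation: str) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency with zero diagonal for one relation."""
        if relation not in RELATIONS:
            raise GraphSchemaError(f"unknown relation {relation!r}")
        e = self.edges.get(relation, np.zeros((0, 2), dtype=np.int64))
        n = self.n_nodes
        if len(e) == 0:
            return sp.csr_matrix((n, n))
        data = np.ones(len(e))
        a = sp.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
        a = a + a.T
        a.setdiag(0)
        a.eliminate_zeros()
        a = a.tocsr()
        a.data[:] = 1.0
        return a

    def combined_adjacency(self) -> sp.csr_matrix:
        n = self.n_nodes
        out = sp.csr_matrix((n, n))
        for r in RELATIONS:
            out = out + self.adjacency(r)
        out.data[:] = 1.0
        return out

    def directed_edge_list(self):
        """All edges as (src, dst, relation_id), both directions; used by the
        aggregator, which sends a message along every directed arc."""
        srcs, dsts, rels = [], [], []
        for ri, r in enumerate(RELATIONS):
            e = self.edges.get(r, np.zeros((0, 2), dtype=np.int64))
            if len(e) == 0:
                continue
            srcs.append(e[:, 0]); dsts.append(e[:, 1]); rels.append(np.full(len(e), ri))
            srcs.append(e[:, 1]); dsts.append(e[:, 0]); rels.append(np.full(len(e), ri))
        if not srcs:
            z = np.zeros(0, dtype=np.int64)
            return z, z, z
        return (np.concatenate(srcs), np.concatenate(dsts), np.concatenate(rels))

    def interaction_text(self, u: int, v: int) -> str | None:
        """Verbatim description on the drug-drug edge (u, v), if any."""
        e = self.edges.get("drug_drug")
        texts = self.edge_attrs.get("drug_drug")
        if e is None or texts is None:
            return None
        for (a, b), t in zip(e, texts):
            if {a, b} == {u, v}:
                return t
        return None

    def validate(self):
        n = self.n_nodes
        # contiguous type blocks in drug < protein < pathway order
        if not np.all(np.diff(self.node_type) >= 0):
            raise GraphSchemaError("node ids must form contiguous blocks drug < protein < pathway")
        for r, e in self.edges.items():
            if r not in RELATIONS:
                raise GraphSchemaError(f"unknown relation {r!r}")
            if len(e) == 0:
                continue
            if e.min() < 0 or e.max() >= n:
                raise GraphSchemaError(f"edge endpoint out of range in {r}")
            s_t, d_t = RELATION_SCHEMA[r]
            types = {NODE_TYPES[self.node_type[x]] for x in e.ravel()}
            if not types <= {s_t, d_t}:
                raise GraphSchemaError(f"relation {r} joins node types {types} outside its schema")
        if self.X is not None:
            if self.X.shape[0] != n:
                raise GraphSchemaError("X must have one row per node")
            if not np.all(np.isfinite(self.X)):
                raise GraphSchemaError("X contains non-finite entries")
        return self


@dataclass(frozen=True)
class LabeledPair:
    drug: int
    protein: int
    label: int
    negative_source: str = "none"  # none | same_family | pathway_informed | balanced


@dataclass
class SplitSpec:
    mode: str  # random | unseen_drug | unseen_protein
    k: int
    fold_of: np.ndarray  # test-fold index per pair
    validation: list  # per fold: index array of validation pairs (subset of train)

    def train_test(self, fold: int):
        test = np.flatnonzero(self.fold_of == fold)
        train = np.flatnonzero(self.fold_of != fold)
        val = self.validation[fold]
        train = np.setdiff1d(train, val)
        return train, val, test


# ----------------------------------------------------------------- features
def _hash_tokens(tokens, width: int) -> np.ndarray:
    """Deterministic feature hashing of string tokens into `width` buckets."""
    import hashlib

    v = np.zeros(width, dtype=np.float32)
    for tok in tokens:
        h = int(hashlib.md5(tok.encode()).hexdigest()[:8], 16)
        v[h % width] += 1.0
    return v


def _drug_features(record: dict, width: int = 40) -> np.ndarray:
    """Hashed descriptor + Morgan-substructure vector for one drug record."""
    smiles = record.get("smiles", "")
    desc = np.zeros(8, dtype=np.float32)
    bits = np.zeros(width - 8, dtype=np.float32)
    if smiles:
        try:
            from rdkit import Chem
            from rdkit.Chem import Descriptors, rdFingerprintGenerator

            mol = Chem.MolFromSmiles(smiles)
        except Exception:  # pragma: no cover - rdkit import issues
            mol = None
        if mol is not None:
            desc = np.array(
                [
                    Descriptors.MolWt(mol) / 500.0,
                    Descriptors.MolLogP(mol) / 5.0,
                    Descriptors.TPSA(mol) / 100.0,
                    Descriptors.NumRotatableBonds(mol) / 10.0,
                    Descriptors.NumHDonors(mol) / 5.0,
                    Descriptors.NumHAcceptors(mol) / 10.0,
                    Descriptors.RingCount(mol) / 5.0,
                    sum(a.GetIsAromatic() for a in mol.GetAtoms()) / 20.0,
                ],
                dtype=np.float32,
            )
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=width - 8)
            fp = gen.GetFingerprint(mol)
            bits = np.array(fp, dtype=np.float32)
    return np.concatenate([desc, bits])


def _protein_features(record: dict) -> np.ndarray:
    seq = record.get("sequence", "")
    comp = np.zeros(20, dtype=np.float32)
    for ch in seq:
        i = _AMINO_ACIDS.find(ch)
        if i >= 0:
            comp[i] += 1.0
    if len(seq):
        comp /= len(seq)
    return np.concatenate([comp, [min(len(seq), 1000) / 200.0]]).astype(np.float32)


def build_node_features(graph: HeteroGraph) -> np.ndarray:
    """Initial X: type one-hot || drug descriptor hash || amino-acid
    composition || hashed pathway category, zero outside a node's own block."""
    n = graph.n_nodes
    d_drug, d_prot, d_pw = 40, 21, 8
    X = np.zeros((n, 3 + d_drug + d_prot + d_pw), dtype=np.float32)
    for i in range(n):
        t = graph.node_type[i]
        X[i, t] = 1.0
        rec = graph.records[i]
        if NODE_TYPES[t] == "drug":
            X[i, 3 : 3 + d_drug] = _drug_features(rec, d_drug)
        elif NODE_TYPES[t] == "protein":
            X[i, 3 + d_drug : 3 + d_drug + d_prot] = _protein_features(rec)
        else:
            X[i, 3 + d_drug + d_prot :] = _hash_tokens([rec.get("category", "")], d_pw)
    return X


# ------------------------------------------------------------------ TSV I/O
TSV_NODE_COLUMNS = ["id", "type", "name", "smiles", "sequence", "family", "state", "groups"]
TSV_EDGE_COLUMNS = ["src", "dst", "relation", "action", "text_ref"]


def save_tsv_graph(graph: HeteroGraph, out_dir: str | Path, pairs: list | None = None):
    """Write nodes.tsv / edges.tsv (+ labels.tsv, interactions_text.tsv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(graph.records):
        rows.append(
            {
                "id": i,
                "type": NODE_TYPES[graph.node_type[i]],
                "name": rec.get("name", f"node{i}"),
                "smiles": rec.get("smiles", ""),
                "sequence": rec.get("sequence", ""),
                # pathway nodes persist their category through this column
                "family": rec.get("family", rec.get("category", "")),
                "state": rec.get("state", ""),
                "groups": "|".join(rec.get("groups", [])),
            }
        )
    pd.DataFrame(rows, columns=TSV_NODE_COLUMNS).to_csv(out / "nodes.tsv", sep="\t", index=False)

    erows, trows = [], []
    for r in RELATIONS:
        e = graph.edges.get(r, np.zeros((0, 2), dtype=np.int64))
        attrs = graph.edge_attrs.get(r, [None] * len(e))
        for j, (u, v) in enumerate(e):
            action, text_ref = "", ""
            if r == "drug_target" and attrs[j] is not None:
                action = attrs[j]
            if r == "drug_drug" and attrs[j] is not None:
                text_ref = f"t{len(trows)}"
                trows.append({"edge_id": text_ref, "description": attrs[j]})
            erows.append({"src": u, "dst": v, "relation": r, "action": action, "text_ref": text_ref})
    pd.DataFrame(erows, columns=TSV_EDGE_COLUMNS).to_csv(out / "edges.tsv", sep="\t", index=False)
    pd.DataFrame(trows, columns=["edge_id", "description"]).to_csv(
        out / "interactions_text.tsv", sep="\t", index=False
    )
    if pairs is not None:
        pd.DataFrame(
            [
                {"drug": p.drug, "protein": p.protein, "label": p.label, "source": p.negative_source}
                for p in pairs
            ],
            columns=["drug", "protein", "label", "source"],
        ).to_csv(out / "labels.tsv", sep="\t", index=False)
    # FASTA for protein sequences
    with open(out / "proteins.fasta", "w") as fh:
        for i in graph.nodes_of_type("protein"):
            rec = graph.records[i]
            fh.write(f">{rec.get('name', i)} id={i}\n{rec.get('sequence', '')}\n")


def load_tsv_graph(in_dir: str | Path) -> HeteroGraph:
    """Read the TSV dialect back into a HeteroGraph (round-trips save_tsv_graph)."""
    d = Path(in_dir)
    nodes = pd.read_csv(d / "nodes.tsv", sep="\t", keep_default_na=False)
    edges = pd.read_csv(d / "edges.tsv", sep="\t", keep_default_na=False)
    texts = {}
    tpath = d / "interactions_text.tsv"
    if tpath.exists():
        tdf = pd.read_csv(tpath, sep="\t", keep_default_na=False)
        texts = dict(zip(tdf["edge_id"], tdf["description"]))

    order = np.argsort([NODE_TYPES.index(t) for t in nodes["type"]], kind="stable")
    if not np.array_equal(order, np.arange(len(nodes))):
        raise GraphSchemaError("nodes.tsv ids must be ordered drug < protein < pathway")
    node_type = np.array([NODE_TYPES.index(t) for t in nodes["type"]], dtype=np.int64)
    records = []
    for _, row in nodes.iterrows():
        rec = {"name": row["name"]}
        if row["type"] == "drug":
            rec.update(smiles=row["smiles"], state=row["state"],
                       groups=[g for g in str(row["groups"]).split("|") if g])
        elif row["type"] == "protein":
            rec.update(sequence=row["sequence"], family=row["family"])
        else:
            rec.update(category=row["family"] or "pathway")
        records.append(rec)

    known = set(nodes["id"].astype(int))
    edict: dict[str, list] = {r: [] for r in RELATIONS}
    attrs: dict[str, list] = {"drug_target": [], "drug_drug": []}
    for _, row in edges.iterrows():
        r = row["relation"]
        if r not in RELATIONS:
            raise GraphSchemaError(f"unknown relation {r!r} in edges.tsv")
        u, v = int(row["src"]), int(row["dst"])
        for x in (u, v):
            if x not in known:
                raise GraphSchemaError(f"edges.tsv references unknown node id {x}")
        edict[r].append((u, v))
        if r == "drug_target":
            attrs["drug_target"].append(row["action"] or "unknown")
        if r == "drug_drug":
            attrs["drug_drug"].append(texts.get(row["text_ref"], ""))
    graph = HeteroGraph(
        node_type=node_type,
        records=records,
        edges={r: np.array(e, dtype=np.int64).reshape(-1, 2) for r, e in edict.items()},
        edge_attrs=attrs,
    )
    graph.X = build_node_features(graph)
    return graph.validate()


def load_labels(in_dir: str | Path) -> list:
    df = pd.read_csv(Path(in_dir) / "labels.tsv", sep="\t", keep_default_na=False)
    return [
        LabeledPair(int(r["drug"]), int(r["protein"]), int(r["label"]), str(r["source"]) or "none")
        for _, r in df.iterrows()
    ]


# --------------------------------------------------------------- XML parsing
def _text(el, tag: str, default: str = "") -> str:
    child = el.find(tag)
    return child.text.strip() if child is not None and child.text else default


def parse_drugbank_xml(path: str | Path, focal_ids: list | None = None) -> HeteroGraph:
    """Parse a DrugBank-dialect XML subset into a HeteroGraph.

    One drug node per ``<drug>`` (all ``<drugbank-id>`` values recorded, the
    primary one identifying), one protein node per distinct polypeptide, one
    pathway node per distinct ``<pathways>`` entry.  Interaction descriptions
    are retained verbatim on drug-drug edges for safety-penalty parsing.
    ``focal_ids`` (external protein ids, e.g. UniProt accessions) are verified
    present; all other nodes are retained.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as err:
        raise XMLParseError(f"malformed XML at line {err.lineno}: {err.msg}") from err
    root = tree.getroot()

    drug_records, drug_ids = [], {}  # any drugbank-id -> drug index
    prot_records, prot_ids = [], {}  # polypeptide id -> protein index
    pw_records, pw_ids = [], {}
    dt_edges, dt_actions = [], []
    dd_edges_raw = []  # (drug_idx, partner drugbank-id, description)
    dpw_edges, pwt_edges = set(), set()

    for drug_el in root.iter("drug"):
        ids = [e.text.strip() for e in drug_el.findall("drugbank-id") if e.text]
        if not ids:
            raise RecordValidationError(
                f"<drug> without <drugbank-id> (name={_text(drug_el, 'name', '?')!r})"
            )
        primary = ids[0]
        if primary in drug_ids:
            di = drug_ids[primary]
            drug_records[di].setdefault("ids", []).extend(i for i in ids if i not in drug_records[di]["ids"])
        else:
            di = len(drug_records)
            props = {}
            for prop in drug_el.iter("property"):
                props[_text(prop, "kind")] = _text(prop, "value")
            drug_records.append(
                {
                    "name": _text(drug_el, "name", primary),
                    "ids": list(ids),
                    "state": _text(drug_el, "state"),
                    "groups": [g.text.strip() for g in drug_el.iter("group") if g.text],
                    "smiles": props.get("SMILES", ""),
                    "properties": props,
                    "metabolism": _text(drug_el, "metabolism"),
                    "toxicity": _text(drug_el, "toxicity"),
                }
            )
        for i in ids:
            drug_ids[i] = di

        for target in drug_el.iter("target"):
            poly = target.find("polypeptide")
            if poly is None:
                continue
            pid = poly.get("id") or _text(poly, "name")
            ext_ids = [
                _text(e, "identifier")
                for e in poly.iter("external-identifier")
            ]
            if pid not in prot_ids:
                prot_ids[pid] = len(prot_records)
                prot_records.append(
                    {
                        "name": _text(poly, "name", pid),
                        "external_id": pid,
                        "external_ids": ext_ids,
                        "sequence": _text(poly, "amino-acid-sequence").replace("\n", ""),
                        "family": _text(poly, "family"),
                    }
                )
            actions = [a.text.strip() for a in target.iter("action") if a.text]
            action = actions[0] if actions else "unknown"
            dt_edges.append((di, prot_ids[pid]))
            dt_actions.append(action)

        for pw in drug_el.iter("pathway"):
            name = _text(pw, "name")
            if not name:
                continue
            if name not in pw_ids:
                pw_ids[name] = len(pw_records)
                pw_records.append({"name": name, "category": _text(pw, "category", "pathway")})
            dpw_edges.add((di, pw_ids[name]))
            for uid in pw.iter("uniprot-id"):
                if uid.text:
                    pwt_edges.add((pw_ids[name], uid.text.strip()))

        for inter in drug_el.iter("drug-interaction"):
            partner = _text(inter, "drugbank-id")
            desc = _text(inter, "description")
            if partner:
                dd_edges_raw.append((di, partner, desc))

    n_d, n_p = len(drug_records), len(prot_records)
    # resolve pathway->target edges: uniprot ids against polypeptide ids / external ids
    ext_map = {}
    for j, rec in enumerate(prot_records):
        ext_map[rec["external_id"]] = j
        for e in rec["external_ids"]:
            ext_map[e] = j
    pwt_resolved = {(pw, ext_map[uid]) for pw, uid in pwt_edges if uid in ext_map}

    if focal_ids:
        missing = [f for f in focal_ids if f not in ext_map]
        if missing:
            raise RecordValidationError(f"focal protein ids not present in XML: {missing}")

    dd_edges, dd_texts, seen_dd = [], [], set()
    for di, partner, desc in dd_edges_raw:
        if partner not in drug_ids:
            logger.warning("drug-interaction partner %s not in file; skipped", partner)
            continue
        dj = drug_ids[partner]
        if di == dj or (min(di, dj), max(di, dj)) in seen_dd:
            continue
        seen_dd.add((min(di, dj), max(di, dj)))
        dd_edges.append((di, dj))
        dd_texts.append(desc)

    node_type = np.array([0] * n_d + [1] * n_p + [2] * len(pw_records), dtype=np.int64)
    records = drug_records + prot_records + pw_records

    def off_p(j):
        return n_d + j

    def off_w(j):
        return n_d + n_p + j

    edges = {
        "drug_target": np.array([(d, off_p(p)) for d, p in dt_edges], dtype=np.int64).reshape(-1, 2),
        "drug_drug": np.array(dd_edges, dtype=np.int64).reshape(-1, 2),
        "drug_pathway": np.array(
            sorted((d, off_w(w)) for d, w in dpw_edges), dtype=np.int64
        ).reshape(-1, 2),
        "pathway_target": np.array(
            sorted((off_w(w), off_p(p)) for w, p in pwt_resolved), dtype=np.int64
        ).reshape(-1, 2),
    }
    graph = HeteroGraph(
        node_type=node_type,
        records=records,
        edges=edges,
        edge_attrs={"drug_target": dt_actions, "drug_drug": dd_texts},
    )
    graph.X = build_node_features(graph)
    return graph.validate()


# --------------------------------------------------------- negative sampling
def _family_map(graph: HeteroGraph) -> dict:
    """family tag -> list of protein node ids."""
    fam: dict[str, list] = {}
    for i in graph.nodes_of_type("protein"):
        fam.setdefault(graph.records[i].get("family", ""), []).append(int(i))
    return fam


def sample_negatives(
    graph: HeteroGraph,
    positives: list,
    ratio: float = 2.0,
    mix: dict | None = None,
    seed: int = 0,
    exclude: set | None = None,
) -> list:
    """Biologically-informed negative sampling.

    Strategies: ``same_family`` pairs a drug with proteins from the family of
    one of its true targets (hard decoys), ``pathway_informed`` with proteins
    sharing a pathway with a true target, ``balanced`` equalizes per-entity
    appearance counts between classes.  Emitted negatives never coincide with
    a known positive (`positives` plus the optional `exclude` set) and the
    total is capped at ``ratio * len(positives)`` with ratio <= 5 enforced.
    """
    if ratio <= 0:
        raise ValueError("negative:positive ratio must be > 0")
    if ratio > 5:
        raise ValueError("negative:positive ratio is capped at 5:1")
    mix = mix or {"same_family": 0.4, "pathway_informed": 0.3, "balanced": 0.3}
    rng = np.random.default_rng(seed)

    pos_pairs = {(p.drug, p.protein) for p in positives}
    forbidden = set(pos_pairs)
    if exclude:
        forbidden |= set(exclude)

    proteins = [int(i) for i in graph.nodes_of_type("protein")]
    fam = _family_map(graph)
    targets_of: dict[int, list] = {}
    for p in positives:
        targets_of.setdefault(p.drug, []).append(p.protein)

    pw_adj = graph.adjacency("pathway_target")

    def pathway_candidates(drug: int) -> list:
        cands: set[int] = set()
        for t in targets_of.get(drug, []):
            for pw in pw_adj.getcol(t).nonzero()[0]:
                cands.update(int(x) for x in pw_adj.getrow(pw).nonzero()[1])
        return sorted(cands)

    n_total = int(round(ratio * len(positives)))
    quota = {s: int(round(f * n_total)) for s, f in mix.items()}
    # rounding may overshoot; trim deterministically
    while sum(quota.values()) > n_total:
        quota[max(quota, key=quota.get)] -= 1

    out: list[LabeledPair] = []
    chosen: set[tuple[int, int]] = set()
    drugs_with_pos = sorted(targets_of)

    def try_add(drug: int, prot: int, source: str) -> bool:
        if prot is None or (drug, prot) in forbidden or (drug, prot) in chosen:
            return False
        chosen.add((drug, prot))
        out.append(LabeledPair(drug, prot, 0, source))
        return True

    # same-family and pathway-informed quotas
    for source in ("same_family", "pathway_informed"):
        want = quota.get(source, 0)
        attempts = 0
        while want > 0 and attempts < 50 * max(want, 1):
            attempts += 1
            drug = int(rng.choice(drugs_with_pos))
            if source == "same_family":
                cands = []
                for t in targets_of[drug]:
                    cands.extend(fam.get(graph.records[t].get("family", ""), []))
                cands = [c for c in cands if (drug, c) not in forbidden and (drug, c) not in chosen]
                if not cands:
                    cands = [
                        c
                        for c in pathway_candidates(drug)
                        if (drug, c) not in forbidden and (drug, c) not in chosen
                    ]
                    if cands:
                        logger.info(
                            "drug %d: no same-family candidate, falling back to pathway_informed",
                            drug,
                        )
                        if try_add(drug, int(rng.choice(cands)), "pathway_informed"):
                            want -= 1
                    continue
            else:
                cands = [
                    c
                    for c in pathway_candidates(drug)
                    if (drug, c) not in forbidden and (drug, c) not in chosen
                ]
                if not cands:
                    cands = [
                        c for c in proteins if (drug, c) not in forbidden and (drug, c) not in chosen
                    ]
                if not cands:
                    continue
            if try_add(drug, int(rng.choice(cands)), source):
                want -= 1

    # balanced: match per-entity appearance counts between label classes
    want = n_total - len(out)
    drug_slots = [p.drug for p in positives]
    prot_slots = [p.protein for p in positives]
    attempts = 0
    while want > 0 and attempts < 50 * max(want, 1):
        attempts += 1
        drug = int(drug_slots[rng.integers(len(drug_slots))])
        prot = int(prot_slots[rng.integers(len(prot_slots))])
        if try_add(drug, prot, "balanced"):
            want -= 1

    return out


# ---------------------------------------------------------------- splitting
def make_splits(pairs: list, mode: str = "random", k: int = 5, seed: int = 0) -> SplitSpec:
    """Stratified k-fold splits; entity modes keep drug (or protein) id sets
    disjoint between train and test folds.  A fixed validation subset (10% of
    the train pairs, label-stratified) is carved out per fold."""
    if k < 2:
        raise ValueError("fold count k must be >= 2")
    if mode not in ("random", "unseen_drug", "unseen_protein"):
        raise ValueError(f"unknown split mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = len(pairs)
    labels = np.array([p.label for p in pairs])
    fold_of = np.full(n, -1, dtype=np.int64)

    if mode == "random":
        for lab in (0, 1):
            idx = np.flatnonzero(labels == lab)
            rng.shuffle(idx)
            for j, i in enumerate(idx):
                fold_of[i] = j % k
    else:
        key = "drug" if mode == "unseen_drug" else "protein"
        ent = np.array([getattr(p, key) for p in pairs])
        uniq = np.unique(ent)
        if len(uniq) < k:
            raise ValueError(f"{mode}: only {len(uniq)} distinct entities for {k} folds")
        # greedy stratified assignment: big entities first, to the fold with
        # the fewest pairs (ties: fewest positives)
        stats = []
        for e in uniq:
            m = ent == e
            stats.append((int(m.sum()), int(labels[m].sum()), int(e)))
        order = sorted(stats, key=lambda s: (-s[0], -s[1], s[2]))
        fold_pairs = np.zeros(k)
        fold_pos = np.zeros(k)
        ent_fold = {}
        for n_pairs, n_pos, e in order:
            f = int(np.lexsort((fold_pos, fold_pairs))[0])
            ent_fold[e] = f
            fold_pairs[f] += n_pairs
            fold_pos[f] += n_pos
        fold_of = np.array([ent_fold[int(x)] for x in ent], dtype=np.int64)

    validation = []
    for f in range(k):
        train = np.flatnonzero(fold_of != f)
        val_rng = np.random.default_rng(seed * 1000 + f)
        val = []
        for lab in (0, 1):
            idx = train[labels[train] == lab]
            take = max(1, int(round(0.1 * len(idx)))) if len(idx) else 0
            if take:
                val.extend(val_rng.choice(idx, size=take, replace=False))
        validation.append(np.sort(np.array(val, dtype=np.int64)))
    return SplitSpec(mode=mode, k=k, fold_of=fold_of, validation=validation)
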
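"""Seeded synthetic heterogeneous knowledge graphs with a planted DTI signal.

The generator emulates the drug/protein/pathway schema the pipeline ingests
from curated sources, at desk scale and with a known ground truth:

* every protein belongs to a family; family membership shows up both as an
  8-residue planted sequence motif and as a family-specific residue
  composition bias;
* every pathway is "about" one or two families (its latent center is the mean
  of those family centers); drugs inherit their latent from their primary
  pathway plus noise, so pathway membership correlates with latent clusters;
* a (drug, protein) pair is a true interaction iff the bilinear score
  dot(z_drug, z_protein) exceeds a threshold calibrated -- on an independent
  Monte-Carlo draw -- so that roughly ``positive_rate`` of candidate pairs
  are positive;
* drug SMILES come from a bank of hand-validated hydrocarbon templates with
  programmatic substituent swaps; planted pharmacophore substructures
  (amide, hydroxyl, aromatic ring) are switched by the sign of the first
  three latent components, so structure correlates with the label rule;
* drug-drug interaction texts are assembled from templates and, at rate
  ``motif_snippet_rate``, embed one labeled pharmacological risk motif
  (CYP conflicts, P-gp/BCRP, QT/torsade, hepatotoxicity, contraindication,
  severity markers); the generator records exactly what it planted.

A single integer seed drives a hierarchical stream (graph / texts / labels),
so identical (config, seed) pairs produce byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kg import HeteroGraph, LabeledPair, build_node_features, save_tsv_graph

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_kg",
    "generate_interaction_texts",
    "write_synthetic_dataset",
    "SMILES_TEMPLATES",
    "MOTIF_SNIPPETS",
]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: hydrocarbon scaffolds with two substitution points; substituents are
#: appended after an atom so the empty substituent stays valid
_SCAFFOLD_CORES = [
    "CCCC{r1}CC{r2}",
    "CC(C)C{r1}CCC{r2}",
    "C1CCCCC1C{r1}C{r2}",
    "C1CCCC1CC{r1}C{r2}",
    "CC(C)(C)CC{r1}C{r2}",
    "CCC(CC){r1}CC{r2}",
    "C1CCCCC1CC(C){r1}C{r2}",
    "CCCCCC{r1}C{r2}",
    "CC1CCCCC1C{r1}CC{r2}",
    "C1CCC(CC1)CC{r1}C{r2}",
]
_DECORATIONS = ["", "C", "CC"]

#: ~30 validated templates: core x alkyl decoration appended at r2 side
SMILES_TEMPLATES = [
    core.replace("{r2}", dec + "{r2}") for core in _SCAFFOLD_CORES for dec in _DECORATIONS
]

_AMIDE, _HYDROXYL, _AROMATIC = "C(=O)N", "O", "c1ccccc1"

#: risk-motif snippet templates keyed by the category the safety parser
#: must recover; {a}/{b} are the two drug names
MOTIF_SNIPPETS = {
    "contraindicated": "Coadministration of {a} with {b} is contraindicated.",
    "serious": "This serious interaction may require immediate therapy modification.",
    "moderate_severity": "This moderate interaction should be monitored closely.",
    "qt": "Coadministration may increase the risk of QT prolongation.",
    "torsade": "Reports of torsade de pointes exist for this combination.",
    "cyp_strong": "{a} is a strong CYP3A4 inhibitor and {b} is a CYP3A4 substrate.",
    "cyp_moderate": "{a} is a moderate CYP2D6 inhibitor while {b} is a CYP2D6 substrate.",
    "transporter": "{a} inhibits P-glycoprotein mediated transport of {b}.",
    "hepatotoxicity": "Combined use may increase the risk of hepatotoxicity.",
}

_BENIGN_TEXTS = [
    "The absorption of {a} can be altered when combined with {b}.",
    "{a} may modestly change the serum concentration of {b}.",
    "No clinically relevant interaction between {a} and {b} has been established.",
    "The excretion rate of {b} may be reduced when given with {a}.",
]


@dataclass(frozen=True)
class SyntheticConfig:
    n_drugs: int = 300
    n_proteins: int = 40
    n_pathways: int = 12
    n_families: int = 2
    latent_dim: int = 8
    positive_rate: float = 0.2
    motif_snippet_rate: float = 0.3
    seed: int = 0
    protein_len: tuple = (80, 200)
    motif_len: int = 8
    drug_noise: float = 0.4
    protein_noise: float = 0.3
    n_focal_families: int = 2

    def validate(self) -> "SyntheticConfig":
        if self.n_drugs < 2:
            raise ValueError("need n_drugs >= 2")
        if not (self.n_proteins >= self.n_families >= 1):
            raise ValueError("need n_proteins >= n_families >= 1")
        if not (0.0 < self.positive_rate < 1.0):
            raise ValueError("positive_rate must be in (0, 1)")
        if not (0.0 <= self.motif_snippet_rate <= 1.0):
            raise ValueError("motif_snippet_rate must be in [0, 1]")
        if self.n_focal_families > self.n_families:
            raise ValueError("n_focal_families cannot exceed n_families")
        return self


@dataclass
class GroundTruth:
    drug_latents: np.ndarray
    protein_latents: np.ndarray
    family_of: dict  # protein node id -> family index
    planted_threshold: float
    focal_families: list = field(default_factory=list)
    drug_pathway: dict = field(default_factory=dict)  # drug id -> primary pathway index
    planted_motifs: list = field(default_factory=list)  # (drug_drug edge idx, category)
    qt_drugs: list = field(default_factory=list)

    def is_positive(self, drug_latent: np.ndarray, protein_latent: np.ndarray) -> bool:
        return float(drug_latent @ protein_latent) > self.planted_threshold

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            drug_latents=np.array(d["drug_latents"]),
            protein_latents=np.array(d["protein_latents"]),
            family_of={int(k): int(v) for k, v in d["family_of"].items()},
            planted_threshold=float(d["planted_threshold"]),
            focal_families=list(d.get("focal_families", [])),
            drug_pathway={int(k): int(v) for k, v in d.get("drug_pathway", {}).items()},
            planted_motifs=[tuple(x) for x in d.get("planted_motifs", [])],
            qt_drugs=list(d.get("qt_drugs", [])),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "drug_latents": self.drug_latents.tolist(),
                "protein_latents": self.protein_latents.tolist(),
                "family_of": {str(k): int(v) for k, v in self.family_of.items()},
                "planted_threshold": self.planted_threshold,
                "focal_families": self.focal_families,
                "drug_pathway": {str(k): int(v) for k, v in self.drug_pathway.items()},
                "planted_motifs": self.planted_motifs,
                "qt_drugs": self.qt_drugs,
            },
            indent=1,
        )


def _streams(seed: int) -> dict:
    """Hierarchical seeded sub-streams: graph / texts / labels."""
    root = np.random.SeedSequence(seed)
    graph_ss, text_ss, label_ss = root.spawn(3)
    return {
        "graph": np.random.default_rng(graph_ss),
        "texts": np.random.default_rng(text_ss),
        "labels": np.random.default_rng(label_ss),
    }


def _family_motif(fam: int, rng_seed: int, length: int) -> str:
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 7919 + fam)))
    return "".join(_AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _protein_sequence(fam: int, cfg: SyntheticConfig, rng: np.random.Generator) -> str:
    lo, hi = cfg.protein_len
    length = int(rng.integers(lo, hi + 1))
    # family-specific residue bias: five preferred residues get tripled weight
    bias = np.ones(20)
    pref = np.random.default_rng(np.random.SeedSequence((cfg.seed, 104729 + fam))).choice(
        20, size=5, replace=False
    )
    bias[pref] = 3.0
    bias /= bias.sum()
    seq = list(_AMINO_ACIDS[i] for i in rng.choice(20, size=length, p=bias))
    motif = _family_motif(fam, cfg.seed, cfg.motif_len)
    pos = int(rng.integers(0, max(1, length - cfg.motif_len)))
    seq[pos : pos + cfg.motif_len] = motif
    return "".join(seq)


def _drug_smiles(latent: np.ndarray, rng: np.random.Generator) -> tuple[str, dict]:
    """Pick a template and plant pharmacophores switched by the latent signs."""
    template = SMILES_TEMPLATES[int(rng.integers(len(SMILES_TEMPLATES)))]
    flags = {
        "amide": bool(latent[0] > 0),
        "hydroxyl": bool(latent[1 % len(latent)] > 0),
        "aromatic": bool(latent[2 % len(latent)] > 0),
    }
    # aromatic ring in the chain, amide at the template end, hydroxyl terminal
    r1 = _AROMATIC if flags["aromatic"] else ""
    r2 = _AMIDE if flags["amide"] else ""
    smiles = template.replace("{r1}", r1).replace("{r2}", r2)
    if flags["hydroxyl"]:
        smiles = smiles + _HYDROXYL
    return smiles, flags


def _validated_smiles(smiles: str) -> str:
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # template bank is hand-validated; guard regressions
        raise AssertionError(f"synthetic template produced invalid SMILES {smiles!r}")
    return Chem.MolToSmiles(mol)


def generate_kg(config: SyntheticConfig) -> tuple[HeteroGraph, list, GroundTruth]:
    """Generate the graph, the positive DTI pairs and the ground truth."""
    cfg = config.validate()
    rngs = _streams(cfg.seed)
    rng = rngs["graph"]
    n_d, n_p, n_w, n_f, dim = (
        cfg.n_drugs,
        cfg.n_proteins,
        cfg.n_pathways,
        cfg.n_families,
        cfg.latent_dim,
    )

    # latent geometry: unit family centers scaled to 2, pathways about 1-2 families
    centers = rng.normal(size=(n_f, dim))
    centers = 2.0 * centers / np.linalg.norm(centers, axis=1, keepdims=True)
    family_of = {i: int(i % n_f) for i in range(n_p)}
    protein_latents = np.stack(
        [centers[family_of[i]] + cfg.protein_noise * rng.normal(size=dim) for i in range(n_p)]
    )
    pw_fams = [
        sorted(rng.choice(n_f, size=int(rng.integers(1, min(2, n_f) + 1)), replace=False))
        for _ in range(n_w)
    ]
    pw_centers = np.stack([centers[f].mean(axis=0) for f in pw_fams]) if n_w else np.zeros((0, dim))
    drug_pathway = {i: int(rng.integers(n_w)) if n_w else -1 for i in range(n_d)}
    drug_latents = np.stack(
        [
            (pw_centers[drug_pathway[i]] if n_w else np.zeros(dim))
            + cfg.drug_noise * rng.normal(size=dim)
            for i in range(n_d)
        ]
    )

    # threshold calibrated on an independent draw of the same generative process
    cal_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 15485863)))
    m = 5000
    cal_pw = cal_rng.integers(n_w, size=m) if n_w else None
    cal_d = (
        pw_centers[cal_pw] + cfg.drug_noise * cal_rng.normal(size=(m, dim))
        if n_w
        else cfg.drug_noise * cal_rng.normal(size=(m, dim))
    )
    cal_f = cal_rng.integers(n_f, size=m)
    cal_p = centers[cal_f] + cfg.protein_noise * cal_rng.normal(size=(m, dim))
    cal_dots = np.einsum("ij,ij->i", cal_d, cal_p)
    threshold = float(np.quantile(cal_dots, 1.0 - cfg.positive_rate))

    # --- records -----------------------------------------------------------
    records, node_type = [], []
    group_bank = ["approved", "investigational", "experimental"]
    qt_drugs = []
    for i in range(n_d):
        smiles, flags = _drug_smiles(drug_latents[i], rng)
        smiles = _validated_smiles(smiles)
        qt = bool(rng.random() < 0.10)
        if qt:
            qt_drugs.append(i)
        records.append(
            {
                "name": f"D{i:04d}",
                "smiles": smiles,
                "state": "solid",
                "groups": [group_bank[int(rng.integers(3))]],
                "pharmacophores": flags,
                "metabolism": "Primarily hepatic, via oxidative pathways.",
                "toxicity": (
                    "May prolong the QT interval at supratherapeutic doses."
                    if qt
                    else "Well tolerated in preclinical models."
                ),
            }
        )
        node_type.append(0)
    for i in range(n_p):
        fam = family_of[i]
        records.append(
            {
                "name": f"P{i:03d}",
                "sequence": _protein_sequence(fam, cfg, rng),
                "family": f"F{fam}",
            }
        )
        node_type.append(1)
    categories = ["signaling", "metabolic", "transport"]
    for j in range(n_w):
        records.append({"name": f"PW{j:02d}", "category": categories[j % 3]})
        node_type.append(2)

    prot_off, pw_off = n_d, n_d + n_p

    # --- labels (planted bilinear rule) ------------------------------------
    dots = drug_latents @ protein_latents.T
    pos_d, pos_p = np.nonzero(dots > threshold)
    pairs = [LabeledPair(int(d), int(prot_off + p), 1, "none") for d, p in zip(pos_d, pos_p)]

    # --- edges --------------------------------------------------------------
    dt_edges = np.array([(p.drug, p.protein) for p in pairs], dtype=np.int64).reshape(-1, 2)
    dpw = {(i, pw_off + drug_pathway[i]) for i in range(n_d) if n_w}
    for i in range(n_d):  # occasional secondary pathway membership
        if n_w > 1 and rng.random() < 0.3:
            extra = int(rng.integers(n_w))
            dpw.add((i, pw_off + extra))
    pwt = set()
    for j in range(n_w):
        members = [prot_off + i for i in range(n_p) if family_of[i] in pw_fams[j]]
        keep = max(1, len(members) // 2)
        chosen = rng.choice(members, size=min(keep, len(members)), replace=False)
        pwt.update((pw_off + j, int(p)) for p in chosen)

    n_dd = min(2 * n_d, n_d * (n_d - 1) // 2)
    dd = set()
    while len(dd) < n_dd:
        u, v = rng.integers(n_d, size=2)
        if u != v:
            dd.add((int(min(u, v)), int(max(u, v))))
    dd_edges = np.array(sorted(dd), dtype=np.int64).reshape(-1, 2)

    graph = HeteroGraph(
        node_type=np.array(node_type, dtype=np.int64),
        records=records,
        edges={
            "drug_target": dt_edges,
            "drug_drug": dd_edges,
            "drug_pathway": np.array(sorted(dpw), dtype=np.int64).reshape(-1, 2),
            "pathway_target": np.array(sorted(pwt), dtype=np.int64).reshape(-1, 2),
        },
        edge_attrs={"drug_target": ["inhibitor"] * len(dt_edges)},
    )

    truth = GroundTruth(
        drug_latents=drug_latents,
        protein_latents=protein_latents,
        family_of={prot_off + i: f for i, f in family_of.items()},
        planted_threshold=threshold,
        focal_families=list(range(cfg.n_focal_families)),
        drug_pathway=drug_pathway,
        qt_drugs=qt_drugs,
    )
    truth.planted_motifs = generate_interaction_texts(graph, cfg, rng=rngs["texts"])
    graph.X = build_node_features(graph)
    graph.validate()
    return graph, pairs, truth


def generate_interaction_texts(
    graph: HeteroGraph, config: SyntheticConfig, rng: np.random.Generator | None = None
) -> list:
    """Attach template-built descriptions to every drug-drug edge.

    With probability ``motif_snippet_rate`` the description embeds exactly one
    labeled risk motif.  Returns the planted (edge index, category) records;
    the texts themselves land in ``graph.edge_attrs['drug_drug']``.
    """
    if rng is None:
        rng = _streams(config.seed)["texts"]
    edges = graph.edges.get("drug_drug", np.zeros((0, 2), dtype=np.int64))
    cats = list(MOTIF_SNIPPETS)
    texts, planted = [], []
    for idx, (u, v) in enumerate(edges):
        a, b = graph.records[u]["name"], graph.records[v]["name"]
        base = _BENIGN_TEXTS[int(rng.integers(len(_BENIGN_TEXTS)))].format(a=a, b=b)
        if rng.random() < config.motif_snippet_rate:
            cat = cats[int(rng.integers(len(cats)))]
            snippet = MOTIF_SNIPPETS[cat].format(a=a, b=b)
            base = f"{base} {snippet}"
            planted.append((int(idx), cat))
        texts.append(base)
    graph.edge_attrs["drug_drug"] = texts
    return planted


def write_synthetic_dataset(config: SyntheticConfig, out_dir: str | Path) -> None:
    """Generate and persist the full TSV/FASTA/JSON dataset dialect."""
    graph, pairs, truth = generate_kg(config)
    out = Path(out_dir)
    save_tsv_graph(graph, out, pairs=pairs)
    (out / "ground_truth.json").write_text(truth.to_json())
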
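"""Graph ingestion, negative sampling and leakage-free splits."""

import numpy as np
import pytest

from spectradti.kg import (
    GraphSchemaError,
    LabeledPair,
    RecordValidationError,
    XMLParseError,
    load_labels,
    load_tsv_graph,
    make_splits,
    parse_drugbank_xml,
    sample_negatives,
    save_tsv_graph,
)
from spectradti.synthetic import SyntheticConfig, generate_kg

FIXTURE_XML = """<?xml version="1.0"?>
<drugbank>
 <drug>
  <drugbank-id primary="true">DB0001</drugbank-id>
  <drugbank-id>APRD0001</drugbank-id>
  <name>alphanib</name>
  <state>solid</state>
  <groups><group>approved</group></groups>
  <calculated-properties>
   <property><kind>SMILES</kind><value>CCO</value></property>
   <property><kind>logP</kind><value>0.2</value></property>
  </calculated-properties>
  <targets>
   <target>
    <id>BE0001</id><name>receptor one</name>
    <actions><action>inhibitor</action></actions>
    <known-action>yes</known-action>
    <polypeptide id="P04626" source="Swiss-Prot">
     <name>her2 kinase</name>
     <amino-acid-sequence>MKVLAAGVK</amino-acid-sequence>
     <family>HER</family>
     <external-identifiers>
      <external-identifier><resource>UniProtKB</resource><identifier>P04626</identifier></external-identifier>
     </external-identifiers>
    </polypeptide>
   </target>
  </targets>
  <pathways>
   <pathway><name>ErbB signaling</name><category>signaling</category>
    <enzymes><uniprot-id>P04626</uniprot-id></enzymes>
   </pathway>
  </pathways>
  <drug-interactions>
   <drug-interaction>
    <drugbank-id>DB0002</drugbank-id><name>betanib</name>
    <description>The serum concentration may rise; coadministration is contraindicated.</description>
   </drug-interaction>
  </drug-interactions>
  <metabolism>Hepatic via CYP3A4.</metabolism>
  <toxicity>May prolong the QT interval.</toxicity>
 </drug>
 <drug>
  <drugbank-id>DB0002</drugbank-id>
  <name>betanib</name>
  <state>solid</state>
  <groups><group>investigational</group></groups>
  <calculated-properties><property><kind>SMILES</kind><value>CC(=O)N</value></property></calculated-properties>
  <targets>
   <target>
    <id>BE0002</id><name>receptor two</name>
    <actions></actions>
    <polypeptide id="P21802" source="Swiss-Prot">
     <name>fgfr2 kinase</name>
     <amino-acid-sequence>MKWVTFISLL</amino-acid-sequence>
     <family>FGFR</family>
    </polypeptide>
   </target>
  </targets>
 </drug>
 <drug>
  <drugbank-id>DB0003</drugbank-id>
  <name>gammanib</name>
  <calculated-properties><property><kind>SMILES</kind><value>c1ccccc1</value></property></calculated-properties>
  <targets>
   <target>
    <id>BE0001b</id><name>receptor one again</name>
    <actions><action>inhibitor</action></actions>
    <polypeptide id="P04626" source="Swiss-Prot">
     <name>her2 kinase</name>
     <amino-acid-sequence>MKVLAAGVK</amino-acid-sequence>
     <family>HER</family>
    </polypeptide>
   </target>
  </targets>
 </drug>
</drugbank>
"""


@pytest.fixture()
def xml_path(tmp_path):
    p = tmp_path / "fixture.xml"
    p.write_text(FIXTURE_XML)
    return p


class TestXMLParsing:
    def test_fixture_counts_and_actions(self, xml_path):
        g = parse_drugbank_xml(xml_path)
        assert len(g.nodes_of_type("drug")) == 3
        assert len(g.nodes_of_type("protein")) == 2
        assert len(g.nodes_of_type("pathway")) == 1
        assert len(g.edges["drug_target"]) == 3
        assert set(g.edge_attrs["drug_target"]) == {"inhibitor", "unknown"}
        # pathway enzymes resolve to the protein's polypeptide id
        assert len(g.edges["pathway_target"]) == 1

    def test_interaction_text_retained_verbatim(self, xml_path):
        g = parse_drugbank_xml(xml_path)
        text = g.interaction_text(0, 1)
        assert text == "The serum concentration may rise; coadministration is contraindicated."

    def test_secondary_id_deduplicates_to_one_node(self, xml_path, tmp_path):
        # a second file where the interaction partner uses the secondary id
        alt = FIXTURE_XML.replace(
            "<drugbank-id>DB0002</drugbank-id><name>betanib</name>",
            "<drugbank-id>DB0002</drugbank-id><name>betanib</name>",
        )
        g = parse_drugbank_xml(tmp_path / "fixture.xml")
        rec = g.records[0]
        assert set(rec["ids"]) == {"DB0001", "APRD0001"}
        assert len(g.nodes_of_type("drug")) == 3

    def test_focal_id_verification(self, xml_path):
        g = parse_drugbank_xml(xml_path, focal_ids=["P04626", "P21802"])
        assert g.n_nodes == 6  # all nodes retained
        with pytest.raises(RecordValidationError):
            parse_drugbank_xml(xml_path, focal_ids=["P99999"])

    def test_malformed_xml_reports_line(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<drugbank><drug></drugbank>")
        with pytest.raises(XMLParseError, match="line"):
            parse_drugbank_xml(bad)

    def test_drug_without_id_is_a_record_error(self, tmp_path):
        p = tmp_path / "noid.xml"
        p.write_text("<drugbank><drug><name>anon</name></drug></drugbank>")
        with pytest.raises(RecordValidationError, match="anon"):
            parse_drugbank_xml(p)

    def test_parse_is_idempotent(self, xml_path):
        g1, g2 = parse_drugbank_xml(xml_path), parse_drugbank_xml(xml_path)
        for r in g1.edges:
            np.testing.assert_array_equal(g1.edges[r], g2.edges[r])
        np.testing.assert_allclose(g1.X, g2.X)


class TestTSVRoundTrip:
    def test_synthetic_round_trip(self, tmp_path, small_kg):
        _, graph, positives, _ = small_kg
        save_tsv_graph(graph, tmp_path, pairs=positives)
        back = load_tsv_graph(tmp_path)
        assert back.n_nodes == graph.n_nodes
        np.testing.assert_array_equal(back.node_type, graph.node_type)
        for r in graph.edges:
            np.testing.assert_array_equal(back.edges[r], graph.edges[r])
        assert back.edge_attrs["drug_drug"] == graph.edge_attrs["drug_drug"]
        labels = load_labels(tmp_path)
        assert labels == positives
        # second round trip is exact (ingestion idempotence)
        save_tsv_graph(back, tmp_path / "again")
        again = load_tsv_graph(tmp_path / "again")
        np.testing.assert_allclose(again.X, back.X)

    def test_unknown_node_reference_is_schema_error(self, tmp_path, small_kg):
        _, graph, _, _ = small_kg
        save_tsv_graph(graph, tmp_path)
        edges = (tmp_path / "edges.tsv").read_text().splitlines()
        edges.append("9999\t0\tdrug_target\tinhibitor\t")
        (tmp_path / "edges.tsv").write_text("\n".join(edges) + "\n")
        with pytest.raises(GraphSchemaError, match="9999"):
            load_tsv_graph(tmp_path)

    def test_empty_pathway_table_still_supports_spse(self, tmp_path):
        from spectradti.spectral import build_operator, compute_spectral_basis

        cfg = SyntheticConfig(n_drugs=10, n_proteins=4, n_pathways=0, seed=2)
        graph, _, _ = generate_kg(cfg)
        assert len(graph.nodes_of_type("pathway")) == 0
        save_tsv_graph(graph, tmp_path)
        back = load_tsv_graph(tmp_path)
        basis = compute_spectral_basis(build_operator(back), d_eig=6)
        assert basis.phi.shape[0] == back.n_nodes


class TestNegativeSampling:
    def test_ratio_cap_and_no_positive_overlap_on_many_graphs(self):
        for seed in range(20):
            cfg = SyntheticConfig(n_drugs=20, n_proteins=8, n_pathways=3,
                                  n_families=2, seed=seed)
            graph, positives, _ = generate_kg(cfg)
            negs = sample_negatives(graph, positives, ratio=5.0, seed=seed)
            assert len(negs) <= 5 * len(positives)
            pos_set = {(p.drug, p.protein) for p in positives}
            assert all((n.drug, n.protein) not in pos_set for n in negs)
            assert all(n.label == 0 for n in negs)
            assert {n.negative_source for n in negs} <= {
                "same_family", "pathway_informed", "balanced"
            }

    def test_same_family_negatives_share_a_family(self, small_kg):
        _, graph, positives, _ = small_kg
        negs = sample_negatives(graph, positives, ratio=2.0, seed=0)
        targets_of = {}
        for p in positives:
            targets_of.setdefault(p.drug, []).append(p.protein)
        for n in negs:
            if n.negative_source != "same_family":
                continue
            fams = {graph.records[t]["family"] for t in targets_of[n.drug]}
            assert graph.records[n.protein]["family"] in fams

    def test_balanced_sampling_tracks_entity_counts(self, small_kg):
        _, graph, positives, _ = small_kg
        negs = sample_negatives(
            graph, positives, ratio=1.0, mix={"balanced": 1.0}, seed=0
        )
        # balanced negatives draw entities proportionally to their positive
        # appearance counts; drugs with no positives never appear
        pos_drugs = {p.drug for p in positives}
        assert {n.drug for n in negs} <= pos_drugs

    def test_invalid_ratio_rejected(self, small_kg):
        _, graph, positives, _ = small_kg
        with pytest.raises(ValueError):
            sample_negatives(graph, positives, ratio=0.0)
        with pytest.raises(ValueError):
            sample_negatives(graph, positives, ratio=6.0)

    def test_exclude_set_is_respected(self, small_kg):
        _, graph, positives, truth = small_kg
        prot_off = 30
        exclude = {
            (d, prot_off + j)
            for d in range(30)
            for j in range(10)
            if truth.drug_latents[d] @ truth.protein_latents[j] > truth.planted_threshold
        }
        negs = sample_negatives(graph, positives, ratio=2.0, seed=1, exclude=exclude)
        assert all((n.drug, n.protein) not in exclude for n in negs)


class TestSplits:
    def _pairs(self, n_drugs=12, n_prot=8, seed=0):
        rng = np.random.default_rng(seed)
        pairs = []
        for d in range(n_drugs):
            for p in rng.choice(n_prot, size=4, replace=False):
                pairs.append(LabeledPair(d, n_drugs + int(p), int(rng.random() < 0.4)))
        return pairs

    @pytest.mark.parametrize("mode,key", [
        ("unseen_drug", "drug"), ("unseen_protein", "protein"),
    ])
    def test_entity_modes_have_disjoint_entities(self, mode, key):
        pairs = self._pairs()
        spec = make_splits(pairs, mode=mode, k=5, seed=0)
        for f in range(5):
            tr, val, te = spec.train_test(f)
            train_ents = {getattr(pairs[i], key) for i in np.concatenate([tr, val])}
            test_ents = {getattr(pairs[i], key) for i in te}
            assert train_ents & test_ents == set()

    def test_every_pair_in_exactly_one_test_fold(self):
        pairs = self._pairs()
        for mode in ("random", "unseen_drug", "unseen_protein"):
            spec = make_splits(pairs, mode=mode, k=5, seed=0)
            covered = np.concatenate([np.flatnonzero(spec.fold_of == f) for f in range(5)])
            assert sorted(covered) == list(range(len(pairs)))

    def test_validation_subset_of_train_and_fixed(self):
        pairs = self._pairs()
        spec = make_splits(pairs, mode="random", k=4, seed=3)
        spec2 = make_splits(pairs, mode="random", k=4, seed=3)
        for f in range(4):
            tr, val, te = spec.train_test(f)
            assert set(val) & set(te) == set()
            np.testing.assert_array_equal(spec.validation[f], spec2.validation[f])

    def test_two_folds_on_four_proteins_hold_out_two_each(self):
        pairs = []
        for d in range(8):
            for p in range(4):
                pairs.append(LabeledPair(d, 100 + p, (d + p) % 2))
        spec = make_splits(pairs, mode="unseen_protein", k=2, seed=0)
        for f in range(2):
            _, _, te = spec.train_test(f)
            assert len({pairs[i].protein for i in te}) == 2

    def test_random_split_is_label_stratified(self):
        pairs = self._pairs(seed=5)
        spec = make_splits(pairs, mode="random", k=5, seed=1)
        global_frac = np.mean([p.label for p in pairs])
        for f in range(5):
            te = np.flatnonzero(spec.fold_of == f)
            frac = np.mean([pairs[i].label for i in te])
            assert abs(frac - global_frac) <= 0.1 * global_frac + 0.05

    def test_errors(self):
        pairs = self._pairs()
        with pytest.raises(ValueError):
            make_splits(pairs, k=1)
        few = [LabeledPair(0, 10, 1), LabeledPair(1, 10, 0)]
        with pytest.raises(ValueError):
            make_splits(few, mode="unseen_protein", k=2)
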
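"""Combination design: coverage ranking, pair scoring, Bliss proxy, and the
lexicon-based safety penalty.

The pair score for a HER2-oriented agent d_h and an FGFR2b-oriented agent d_f

    S_pair = w1 p'_HER2(d_h) + w2 p'_FGFR2b(d_f) + w3 sigma(sim(h_dh, h_df)) - psi

combines calibrated single-target coverage, embedding similarity (cosine on
the drugs' aggregated embeddings, squashed by a logistic) and an additive
safety penalty psi parsed from interaction/metabolism/toxicity text.  A
Bliss-independence proxy S_Bliss = 1 - (1 - p1)(1 - p2) is reported
alongside.  Contraindicated pairs are hard-dropped (the infinite-weight
term), all other motifs down-rank through psi:

    psi = a_Sev N_serious + a_Mod N_moderate + b_QT 1_QT
          + g_CYP 1_CYPconflict + g_PgP/BCRP 1_transporter + r_hep 1_hep

with b_QT escalated from 2 to 3 when both drugs carry QT risk or torsade de
pointes is mentioned, and g_CYP = 2 for strong / 1 for moderate conflicts.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SafetyWeights",
    "RiskMotifHits",
    "PairTexts",
    "PairScore",
    "load_lexicon",
    "parse_safety_motifs",
    "safety_penalty",
    "bliss_score",
    "single_agent_scan",
    "pair_scores",
    "write_pairs_tsv",
    "read_pairs_tsv",
]


@dataclass(frozen=True)
class SafetyWeights:
    """Default motif weights; the contraindication term is a hard drop and is
    never summed."""

    alpha_sev: float = 3.0
    alpha_mod: float = 1.0
    beta_qt: float = 2.0
    beta_qt_escalated: float = 3.0
    gamma_cyp_strong: float = 2.0
    gamma_cyp_moderate: float = 1.0
    gamma_transporter: float = 1.0
    rho_hep: float = 1.0


@dataclass
class RiskMotifHits:
    n_serious: int = 0
    n_moderate: int = 0
    qt_pair: bool = False  # any QT mention relevant to the pair
    qt_drug_a: bool = False
    qt_drug_b: bool = False
    torsade: bool = False
    cyp_conflict: str = "none"  # none | moderate | strong
    transporter: bool = False
    hepatotoxicity: bool = False
    contraindicated: bool = False
    snippets: list = field(default_factory=list)  # (category, source, text)

    def validate(self):
        flags = {
            "serious": self.n_serious > 0,
            "moderate": self.n_moderate > 0,
            "qt": self.qt_pair,
            "torsade": self.torsade,
            "cyp": self.cyp_conflict != "none",
            "transporter": self.transporter,
            "hepatotoxicity": self.hepatotoxicity,
            "contraindicated": self.contraindicated,
        }
        have = {c for c, _, _ in self.snippets}
        for cat, on in flags.items():
            if on and cat not in have:
                raise AssertionError(f"flag {cat} set without a recorded snippet")
        return self


@dataclass
class PairTexts:
    """The text fields feeding the parser for one drug pair."""

    interaction: str = ""
    metabolism_a: str = ""
    metabolism_b: str = ""
    toxicity_a: str = ""
    toxicity_b: str = ""


def load_lexicon(path: str | Path | None = None) -> dict:
    if path is None:
        ref = resources.files("spectradti") / "lexicons" / "safety_lexicon.json"
        text = ref.read_text()
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"lexicon file not found: {p}")
        text = p.read_text()
    return json.loads(text)


def _normalize(text: str) -> str:
    """Lowercase and collapse punctuation (hyphens kept for terms like p-gp)."""
    t = text.lower()
    t = re.sub(r"[^\w\s\-]", " ", t)
    return re.sub(r"\s+", " ", t).strip()


def _snippet(original: str, term: str, width: int = 60) -> str:
    i = _normalize(original).find(term)
    if i < 0:
        return original[: 2 * width]
    # map via normalized index is approximate; clamp on the original string
    a, b = max(0, i - width), min(len(original), i + len(term) + width)
    return original[a:b]


def _find_terms(text: str, terms: list) -> list:
    norm = _normalize(text)
    return [t for t in terms if t in norm]


def parse_safety_motifs(texts: PairTexts, lexicon: dict | None = None) -> RiskMotifHits:
    """Match the pair's interaction/metabolism/toxicity text against the
    curated lexicons; every raised flag records its triggering snippet."""
    lex = lexicon if lexicon is not None else load_lexicon()
    hits = RiskMotifHits()
    sources = {
        "drug-interactions": texts.interaction,
        "metabolism:a": texts.metabolism_a,
        "metabolism:b": texts.metabolism_b,
        "toxicity:a": texts.toxicity_a,
        "toxicity:b": texts.toxicity_b,
    }

    def record(cat, source, term):
        hits.snippets.append((cat, source, _snippet(sources[source], term)))

    # sentence-level severity counts on the interaction description
    sentences = [s.strip() for s in re.split(r"[.;]", texts.interaction) if s.strip()]
    for s in sentences:
        if _find_terms(s, lex["severity_serious"]):
            hits.n_serious += 1
            hits.snippets.append(("serious", "drug-interactions", s[:120]))
        elif _find_terms(s, lex["severity_moderate"]):
            hits.n_moderate += 1
            hits.snippets.append(("moderate", "drug-interactions", s[:120]))

    for source, text in sources.items():
        if not text:
            continue
        for term in _find_terms(text, lex["contraindicated"]):
            hits.contraindicated = True
            record("contraindicated", source, term)
        for term in _find_terms(text, lex["qt"]):
            hits.qt_pair = True
            if source.endswith(":a"):
                hits.qt_drug_a = True
            if source.endswith(":b"):
                hits.qt_drug_b = True
            record("qt", source, term)
        for term in _find_terms(text, lex["torsade"]):
            hits.torsade = True
            hits.qt_pair = True
            record("torsade", source, term)
            hits.snippets.append(("qt", source, _snippet(text, term)))
        for term in _find_terms(text, lex["transporter"]):
            hits.transporter = True
            record("transporter", source, term)
        for term in _find_terms(text, lex["hepatotoxicity"]):
            hits.hepatotoxicity = True
            record("hepatotoxicity", source, term)

    # CYP inhibition-substrate conflicts: same family on both roles
    inh_pat = re.compile(lex["cyp_inhibitor_pattern"])
    sub_pat = re.compile(lex["cyp_substrate_pattern"])
    strong_words = set(lex["cyp_strong_words"])
    inhibitors: dict[str, str] = {}  # family -> strength
    substrates: set[str] = set()
    for source, text in sources.items():
        norm = _normalize(text)
        for strength, fam in inh_pat.findall(norm):
            level = "strong" if strength in strong_words else "moderate"
            if inhibitors.get(fam) != "strong":
                inhibitors[fam] = level
            hits.snippets.append(("cyp", source, _snippet(text, fam)))
        for fam in sub_pat.findall(norm):
            substrates.add(fam)
            hits.snippets.append(("cyp", source, _snippet(text, fam)))
    conflict_fams = set(inhibitors) & substrates
    if conflict_fams:
        hits.cyp_conflict = (
            "strong" if any(inhibitors[f] == "strong" for f in conflict_fams) else "moderate"
        )
    else:
        # drop informational cyp snippets if no conflict materialized
        hits.snippets = [s for s in hits.snippets if s[0] != "cyp"]
    return hits.validate()


def safety_penalty(hits: RiskMotifHits, weights: SafetyWeights = SafetyWeights()):
    """Additive penalty psi and the contraindication hard-drop flag.

    psi is reported even for dropped pairs (audit only)."""
    w = weights
    breakdown = {
        "serious": w.alpha_sev * hits.n_serious,
        "moderate": w.alpha_mod * hits.n_moderate,
        "qt": 0.0,
        "cyp": 0.0,
        "transporter": w.gamma_transporter * hits.transporter,
        "hepatotoxicity": w.rho_hep * hits.hepatotoxicity,
    }
    if hits.qt_pair:
        dual = (hits.qt_drug_a and hits.qt_drug_b) or hits.torsade
        breakdown["qt"] = w.beta_qt_escalated if dual else w.beta_qt
    if hits.cyp_conflict == "strong":
        breakdown["cyp"] = w.gamma_cyp_strong
    elif hits.cyp_conflict == "moderate":
        breakdown["cyp"] = w.gamma_cyp_moderate
    psi = float(sum(breakdown.values()))
    return psi, bool(hits.contraindicated), breakdown


def bliss_score(p1: float, p2: float) -> float:
    """Bliss-independence proxy 1 - (1 - p1)(1 - p2)."""
    return 1.0 - (1.0 - p1) * (1.0 - p2)


_S_MULTI_RULES = {
    "min": lambda a, b: min(a, b),
    "product": lambda a, b: a * b,
    "mean": lambda a, b: 0.5 * (a + b),
}


def single_agent_scan(p_her2: dict, p_fgfr2b: dict, rule: str = "min") -> pd.DataFrame:
    """Rank drugs by dual-target coverage s_multi(d).

    The default rule is min(p'_HER2, p'_FGFR2b): coverage is limited by the
    weaker arm.  Drugs missing either probability are excluded."""
    import logging

    fn = _S_MULTI_RULES[rule]
    rows = []
    for d in sorted(set(p_her2) | set(p_fgfr2b)):
        if d not in p_her2 or d not in p_fgfr2b:
            logging.getLogger(__name__).warning("drug %s missing a probability; excluded", d)
            continue
        rows.append({"drug": d, "p_her2": p_her2[d], "p_fgfr2b": p_fgfr2b[d],
                     "s_multi": fn(p_her2[d], p_fgfr2b[d])})
    df = pd.DataFrame(rows, columns=["drug", "p_her2", "p_fgfr2b", "s_multi"])
    return df.sort_values(["s_multi", "drug"], ascending=[False, True]).reset_index(drop=True)


@dataclass
class PairScore:
    d_h: int
    d_f: int
    p_her2: float
    p_fgfr2b: float
    sim: float
    psi: float
    psi_breakdown: dict
    s_pair: float
    s_bliss: float
    dropped: bool
    snippets: list = field(default_factory=list)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _logistic(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def pair_scores(
    her2_agents: list,
    fgfr_agents: list,
    p_her2: dict,
    p_fgfr2b: dict,
    embeddings: dict,
    texts_for_pair,
    w: tuple = (0.4, 0.4, 0.2),
    weights: SafetyWeights = SafetyWeights(),
    lexicon: dict | None = None,
) -> list:
    """Score all M x M (HER2-oriented, FGFR-oriented) agent pairs.

    `texts_for_pair(d_h, d_f)` supplies the PairTexts the safety parser
    consumes.  Self-pairs are skipped."""
    lex = lexicon if lexicon is not None else load_lexicon()
    out = []
    for dh in her2_agents:
        for df in fgfr_agents:
            if dh == df:
                continue
            hits = parse_safety_motifs(texts_for_pair(dh, df), lex)
            psi, dropped, breakdown = safety_penalty(hits, weights)
            sim = _cosine(embeddings[dh], embeddings[df])
            ph, pf = float(p_her2[dh]), float(p_fgfr2b[df])
            s_pair = w[0] * ph + w[1] * pf + w[2] * _logistic(sim) - psi
            out.append(
                PairScore(
                    d_h=dh, d_f=df, p_her2=ph, p_fgfr2b=pf, sim=sim, psi=psi,
                    psi_breakdown=breakdown, s_pair=float(s_pair),
                    s_bliss=bliss_score(ph, pf), dropped=dropped,
                    snippets=hits.snippets,
                )
            )
    return out


PAIRS_TSV_COLUMNS = [
    "d_h", "d_f", "p_her2_cal", "p_fgfr2b_cal", "sim", "psi", "psi_breakdown",
    "s_pair", "s_bliss", "dropped", "snippets",
]


def write_pairs_tsv(table: list, path: str | Path) -> None:
    """Ranked TSV, S_pair descending with (d_h, d_f) tie-break; dropped pairs
    form a trailing section and carry no rank."""
    keep = sorted((p for p in table if not p.dropped), key=lambda p: (-p.s_pair, p.d_h, p.d_f))
    dropped = sorted((p for p in table if p.dropped), key=lambda p: (p.d_h, p.d_f))
    rows = []
    for p in keep + dropped:
        rows.append(
            {
                "d_h": p.d_h, "d_f": p.d_f,
                "p_her2_cal": f"{p.p_her2:.6f}", "p_fgfr2b_cal": f"{p.p_fgfr2b:.6f}",
                "sim": f"{p.sim:.6f}", "psi": f"{p.psi:.4f}",
                "psi_breakdown": json.dumps(p.psi_breakdown),
                "s_pair": f"{p.s_pair:.6f}", "s_bliss": f"{p.s_bliss:.6f}",
                "dropped": int(p.dropped),
                "snippets": json.dumps(p.snippets),
            }
        )
    pd.DataFrame(rows, columns=PAIRS_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path: str | Path) -> list:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(
            PairScore(
                d_h=int(r["d_h"]), d_f=int(r["d_f"]),
                p_her2=float(r["p_her2_cal"]), p_fgfr2b=float(r["p_fgfr2b_cal"]),
                sim=float(r["sim"]), psi=float(r["psi"]),
                psi_breakdown=json.loads(r["psi_breakdown"]),
                s_pair=float(r["s_pair"]), s_bliss=float(r["s_bliss"]),
                dropped=bool(int(r["dropped"])),
                snippets=[tuple(s) for s in json.loads(r["snippets"])],
            )
        )
    return out
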
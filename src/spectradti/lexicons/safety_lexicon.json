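{
  "_comment": "Illustrative curated lexicon for pair-level risk-motif parsing. Terms are matched case-insensitively on punctuation-normalized text. Not a clinical resource.",
  "contraindicated": ["contraindicated", "contraindication"],
  "severity_serious": ["serious interaction", "serious adverse"],
  "severity_moderate": ["moderate interaction"],
  "qt": ["qt prolongation", "prolong the qt", "qtc interval", "herg blockade", "herg inhibition"],
  "torsade": ["torsade de pointes", "torsades de pointes"],
  "transporter": ["p-gp", "p-glycoprotein", "bcrp", "breast cancer resistance protein"],
  "hepatotoxicity": ["hepatotoxicity", "hepatotoxic", "liver injury", "hepatic injury"],
  "cyp_inhibitor_pattern": "(strong|potent|moderate)\\s+(cyp\\w+)\\s+inhibitor",
  "cyp_substrate_pattern": "(cyp\\w+)\\s+substrate",
  "cyp_strong_words": ["strong", "potent"]
}
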
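"""Validate the shipped oligo tables.

The smiFISH probe sets and the anticodon-loop antisense oligos published
with the study ship as CSV fixtures; this checks set sizes, a uniform
22-nt length, the DNA alphabet, and duplicates.
"""

from ncfish import load_aso_table, load_primer_table, load_probe_table, validate_oligos

probes = load_probe_table()
report = validate_oligos(probes, expected_length=22, sets=["Gars1"])
print(f"Gars1 probe set: {report.set_counts['Gars1']} probes, "
      f"lengths {report.set_lengths['Gars1']} nt, passed={report.passed}")

asos = load_aso_table()
report = validate_oligos(asos, expected_length=22)
print(f"ASO table: {report.n_oligos} oligos, lengths "
      f"{sorted({l for v in report.set_lengths.values() for l in v})} nt, "
      f"passed={report.passed}")

primers = load_primer_table()
print(f"primer table: {len(primers)} primers, "
      f"{primers['sequence'].str.len().min()}-"
      f"{primers['sequence'].str.len().max()} nt")
# 24 x 22-nt probes against the target mRNA and 4 x 22-nt ASOs match the
# published design; a failure here would mean a corrupted fixture.
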
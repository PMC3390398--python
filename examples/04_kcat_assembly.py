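"""From raw turnover-number records to one kcat per reaction.

Database exports carry several measurements per enzyme, from several
organisms, some on mutated enzymes.  The assembly rules: drop mutants;
median of own-organism values; else mean over other species; else the
model-wide median.  Provenance is kept so predictions can later be
restricted to reactions with own-organism kinetics.
"""

from momentfba import KcatRecord, assemble_kcats, chain_toy, compute_mw

model = chain_toy(kcats=(1.0, 1.0, 1.0), mws=(1.0, 1.0, 1.0)).model
records = [
    KcatRecord("R1", "Escherichia coli", 5.0),
    KcatRecord("R1", "Escherichia coli", 10.0),
    KcatRecord("R1", "Escherichia coli", 100.0),
    KcatRecord("R1", "Escherichia coli", 999.0, mutant=True),  # filtered out
    KcatRecord("R2", "Saccharomyces cerevisiae", 2.0),
    KcatRecord("R2", "Homo sapiens", 4.0),
    # R3: no records anywhere -> model-wide median fill
]

kcat, provenance, counts = assemble_kcats(records, model, "Escherichia coli")
print("per-reaction kcat (1/s) and provenance:")
for rid in sorted(kcat):
    print(f"  {rid}: {kcat[rid] / 3600.0:6.2f}  [{provenance[rid]}]")
print("provenance counts:", counts)
# R1: median(5, 10, 100) = 10; R2: mean(2, 4) = 3; R3: median(10, 3) = 6.5

seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
print(f"\nMW of a {len(seq)}-residue peptide: {compute_mw(seq):.4f} g/mmol")
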
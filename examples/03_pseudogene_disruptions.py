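"""Detect ORF disruptions in a decaying gene aligned to its intact ortholog.

A 22-nt deletion shifts the reading frame (22 mod 3 = 1) and exposes a
premature stop downstream; a 3-nt in-frame deletion leaves the ORF intact.
"""

from hadalcomp import call_unitary_candidates, detect_disruptions

# a 100-codon CDS; its +1-shifted frame reads TAA downstream of the deletion
cds = "ATG" + "GCT" * 29 + "AAT" * 30 + "CTAACT" + "GCT" * 37 + "TAA"

frameshifted = cds[:90] + "-" * 22 + cds[112:]
report = detect_disruptions("decayed_gene", cds, frameshifted)
print("22-nt deletion:")
for event in report.events:
    print(f"  {event.kind} at position {event.position} (length {event.length})")
print(f"  verdict: {report.verdict}, intact fraction {report.intact_fraction:.2f}")

in_frame = cds[:90] + "---" + cds[93:]
report = detect_disruptions("tolerant_gene", cds, in_frame)
print(f"3-nt in-frame deletion: verdict {report.verdict} (no events)")

# the upstream gate: locus aligned for the reference lineage (>=70% CDS
# coverage) but absent for the focal lineage (<=30%)
coverages = {
    "decayed_gene": {"stickleback": 0.85, "focal": 0.10},
    "intact_gene": {"stickleback": 0.90, "focal": 0.95},
}
candidates = call_unitary_candidates(coverages, ["stickleback"], "focal")
print(f"unitary pseudogene candidates from coverage gate: {candidates}")
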
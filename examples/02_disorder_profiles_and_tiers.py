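"""Per-residue disorder profiles and ADS/PPDR tier classification.

Profiles three archetypal sequences with the built-in windowed
charge–hydropathy predictor, then aggregates each profile to its average
disorder score (ADS, mean per-residue score) and percentage of predicted
disordered residues (PPDR, % of residues scoring > 0.5), and assigns the
standard four-tier label (cut-offs 10%/30% PPDR, 0.15/0.5 ADS).
"""

from idpome.classify import summarize_protein
from idpome.disorder import foldindex_profile

sequences = {
    "globular-like": "MKVLIVFAILVAW" * 8,   # hydrophobic, low charge
    "idp-like": "PESKQGDEKSPEQE" * 8,       # polar/charged, low hydropathy
    "half-and-half": "MKVLIVFAILVAW" * 4 + "PESKQGDEKSPEQE" * 4,
}

print(f"{'protein':<15} {'ADS':>6} {'PPDR %':>7}  tier")
for name, seq in sequences.items():
    summary = summarize_protein(foldindex_profile(seq, name))
    print(f"{name:<15} {summary.ads:6.3f} {summary.ppdr:7.1f}  {summary.tier.value}")
# ADS near 0 = confidently ordered, near 1 = confidently disordered;
# the tier combines both axes, with discordant cases falling to the
# residual "ModeratelyOrderedOrMildlyFlexible" tier.
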
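"""Convert the manual per-HPF TIL criterion to a per-mm^2 tumour density.

The manual method counts TILs in five circular high-power fields of diameter
0.55 mm and calls a case TIL-High at a mean of >= 2 TILs/HPF.  The automated
score normalises by tumour area instead, so the equivalent cut-off depends on
how much of an HPF is tumour.
"""

from itilscore import classify, hpf_equivalent_density, manual_score_classify

print("manual criterion: 2 TILs per HPF (diameter 0.55 mm)")
for frac in (0.4, 0.5, 0.6):
    dens = hpf_equivalent_density(2.0, tumour_fraction=frac, hpf_diameter_mm=0.55)
    print(f"  at {frac:.0%} tumour per HPF -> {dens:.2f} ~ {round(dens)} iTILs/mm^2 tumour")
# At ~50% tumour the manual threshold lands on 17/mm^2 — the binary cut-off
# used for the automated TIL-High/TIL-Low call.

print("classify(16.9, cutoff=17) ->", classify(16.9, 17.0))
print("classify(17.0, cutoff=17) ->", classify(17.0, 17.0))
print("manual counts (0,0,0,5,5)  ->", manual_score_classify([0, 0, 0, 5, 5]))
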
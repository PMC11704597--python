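"""Oxygen-transport arithmetic: from bedside numbers to mixed venous saturation.

Builds one hemodynamic vignette and walks it through the model's algebraic
core: arterial O2 content, pulse-pressure stroke volume, cardiac output, and
the Fick closure for SvO2.
"""

from o2index import arterial_o2_content, cardiac_output, fick_svo2, stroke_volume

# a post-operative adult: 120/80 arterial pressure, HR 80, Hgb 11 g/dL,
# SpO2 97%, whole-body O2 consumption 240 mL/min
sbp, dbp, hr = 120.0, 80.0, 80.0
hgb, sao2, vo2 = 11.0, 0.97, 240.0
k_sv = 3.3  # vascular gain calibrated so this patient sits near CO 5 L/min

cao2 = arterial_o2_content(hgb, sao2)
sv = stroke_volume(sbp, dbp, k_sv)
co = cardiac_output(hr, sv)
svo2 = fick_svo2(sao2, vo2, co, hgb)

print(f"arterial O2 content : {cao2:.2f} mL/dL   (1.34 x Hgb x SaO2)")
print(f"stroke volume       : {sv:.1f} mL       (pulse-pressure law, gain {k_sv})")
print(f"cardiac output      : {co:.2f} L/min")
print(f"mixed venous SvO2   : {100 * svo2:.1f} %")
print()
print("Halving hemoglobin at fixed flow and consumption:")
print(f"  SvO2 -> {100 * fick_svo2(sao2, vo2, co, hgb / 2):.1f} %  "
      "(less O2 carried per litre, so extraction bites deeper)")
print("Doubling O2 consumption (e.g. high fever, shivering):")
print(f"  SvO2 -> {100 * fick_svo2(sao2, 2 * vo2, co, hgb):.1f} %  "
      "(identical: extraction depends on VO2/(CO x Hgb), so doubling VO2")
print("   and halving Hgb are the same insult to venous reserve)")
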
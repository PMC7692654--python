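"""Sequential gastric → intestinal digestion of heat-pretreated extracts.

Simulates four pretreatments with increasing phase rates (stronger preheating
degrades faster during digestion), computes phase-relative retention with the
5 mL + 10 mL intestinal dilution handled at the phase switch, and correlates
anthocyanin loss with antioxidant-activity loss.
"""

import math

from thermokin import loss_correlation, phase_retention, simulate_digestion

# phase rates chosen so 120-min losses follow the published pattern:
# gastric 21/16/32% and near-complete loss at 180 °C; intestinal steeper
pretreatments = {
    "untreated":   (-math.log(0.79) / 120, -math.log(0.88) / 120),
    "80C-40min":   (-math.log(0.84) / 120, -math.log(0.40) / 120),
    "120C-7min":   (-math.log(0.68) / 120, -math.log(0.70) / 120),
    "180C-7min":   (-math.log(0.20) / 120, -math.log(0.17) / 120),
}

courses = []
for i, (label, (kg, ki)) in enumerate(pretreatments.items()):
    gastric, intestinal, _ = simulate_digestion(
        k_gastric=kg, k_intestinal=ki, loss_coupling=0.9,
        noise_cv=0.02, seed=100 + i, pretreatment=label,
    )
    courses += [gastric, intestinal]
    g = phase_retention(gastric)
    it = phase_retention(intestinal)
    g_loss = g[(g.assay == "tac") & (g.time_min == 120)].decrease_pct.iloc[0]
    i_loss = it[(it.assay == "tac") & (it.time_min == 120)].decrease_pct.iloc[0]
    print(f"{label:<10} TAC loss after 120 min: gastric {g_loss:5.1f}%  "
          f"intestinal {i_loss:5.1f}%")

r, p = loss_correlation(courses)
print(f"\npooled anthocyanin-loss vs antioxidant-loss Pearson r = {r:.3f} "
      f"(p = {p:.1e})")
# losses are phase-relative (each phase rebased to its own t = 0); the strong
# positive r reflects the 0.9 loss coupling built into the generator
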
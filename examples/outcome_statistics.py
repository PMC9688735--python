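"""Grade the published oocyte-outcome tables against their static control.

Loads the packaged nuclear-chromatin count table for the native-perfusion
experiment, recomputes the per-cell percentages and the per-category
chi-square significance grades, and prints the headline maturation contrast.
"""

from mivmsim import chi_square_2x2, grade_table
from mivmsim.tables import get_table

table = get_table("nuclear_native")
print("counts (oocytes per nuclear-chromatin category):")
print(table.to_frame(), "\n")
print("percentages (rounded half-up, as reported):")
print(table.percents(), "\n")

grades, pvals = grade_table(table, control_group="CTRL")
print("uncorrected Pearson chi-square vs control (category vs rest):")
print(pvals.round(5), "\n")
print("significance grades (* p<0.05, ** p<0.01, *** p<0.001):")
print(grades, "\n")

mii = table.categories.index("MII")
a, n_a = int(table.row("CTRL")[mii]), int(table.n_evaluated[0])
c, n_c = int(table.row("native_50")[mii]), int(table.n_evaluated[1])
stat, p = chi_square_2x2(a, n_a - a, c, n_c - c)
print(f"headline: MII rate {a}/{n_a} (control) vs {c}/{n_c} (50 uL/min): "
      f"chi2 = {stat:.1f}, p = {p:.2g}")
print("-> perfusing naked COCs collapses the maturation rate (p < 0.001).")
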
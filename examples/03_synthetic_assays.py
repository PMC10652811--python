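"""Generate the two synthetic in vitro assay designs.

Emulates a 5-day drug-synergy plate (5x5 dose matrix, total live-cell
counts) and a 4-day phase-resolved cell-cycle plate (single-drug ladders
plus matched combinations, ~10% phase-unassigned cells) and prints
summary features of each table.
"""

import numpy as np

from cycletrial import default_truth, generate_cellcycle, generate_synergy

truth = default_truth("sensitive_plusDOX")

syn = generate_synergy(truth, seed=42)
print(f"synergy table: {len(syn)} rows "
      f"({syn.dose_F.nunique()}x{syn.dose_P.nunique()} doses, "
      f"{syn.day.nunique()} days, {syn.replicate.nunique()} replicates)")
ctrl = syn[(syn.dose_F == 0) & (syn.dose_P == 0)].groupby("day")["count"].mean()
print("control well mean counts by day:", np.round(ctrl.to_numpy(), 0))
top = syn[(syn.dose_F == 5.2) & (syn.dose_P == 100.0)].groupby("day")["count"].mean()
print("highest-dose well mean counts:  ", np.round(top.to_numpy(), 0))

cc = generate_cellcycle(truth, seed=42)
una = cc[cc.phase == "unassigned"]["count"].sum() / cc["count"].sum()
print(f"\ncell-cycle table: {len(cc)} rows; unassigned share {100*una:.1f}%")
day4 = cc[(cc.day == 4) & (cc.phase == "G1")]
for d_p, grp in day4[day4.dose_F == 0].groupby("dose_P"):
    tot = cc[(cc.day == 4) & (cc.dose_F == 0) & (cc.dose_P == d_p)
             & (cc.phase != "unassigned")]["count"].sum()
    print(f"  palbociclib {d_p:6.1f} nmol/L -> day-4 G1 share "
          f"{100 * grp['count'].sum() / tot:.0f}%")
# G1 share rises with dose: the G1->S checkpoint arrest the model encodes.
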
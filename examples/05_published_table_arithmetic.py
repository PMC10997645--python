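"""Re-aggregate the published Ugandan sub-regional production-loss table.

Loads the published per-sub-region seasonal bean production losses to ozone
(Uganda, 2015, tonnes), recomputes row annual totals and national totals
with the package's loss-table arithmetic, and prints them.
"""

from ozoneyield import aggregate_loss_table, uganda_production_losses_2015

ref = uganda_production_losses_2015()
out = aggregate_loss_table(ref)
print(out.to_string(index=False))
nat = out[out.sub_region == "Total"].iloc[0]
print(f"\nnational totals: season 1 {nat.season1:,.0f} t, "
      f"season 2 {nat.season2:,.0f} t, annual {nat.total:,.0f} t")
print("(the season columns are printed rounded values; their sums can "
      "differ from independently rounded published totals by ~1 t)")
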
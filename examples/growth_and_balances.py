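"""Growth performance and nutrient balances for a feeding-trial tank.

Builds one tank record with the report-table inputs of a 41-day tilapia
growth trial, computes the growth metrics, a marker-based digestibility
coefficient, and the nitrogen/energy partition chains, and prints each with
a line on what it means.
"""

from rearlegacy import (
    CompositionProfile,
    TankGrowthRecord,
    adc,
    energy_balance,
    growth_performance,
    nitrogen_balance,
)

record = TankGrowthRecord(
    n_initial=30, n_final=30, w_initial=7.2, w_final=34.2,
    duration=41, feed_intake=0.76,
)
m = growth_performance(record)
print(f"growth  {m.growth:.2f} g/d      (weight gain per day)")
print(f"SGR     {m.sgr:.1f} %BW/d     (log-ratio growth rate)")
print(f"FCR     {m.fcr:.2f}          (g feed DM per g gain)")
print(f"survival {m.survival:.0f} %")

feed = CompositionProfile(role="feed", yttrium=50.0, crude_protein=400.0)
faeces = CompositionProfile(role="faeces", yttrium=150.0, crude_protein=360.0)
adc_cp = adc(feed, faeces, "crude_protein")
print(f"\nADC crude protein  {adc_cp:.1f} %   "
      "(fraction of ingested protein apparently absorbed, via the inert Y marker)")

nb = nitrogen_balance(feed_intake=0.76, diet_n=55.0, adc_n=adc_cp / 100,
                      body_n_initial=180.0, body_n_final=1100.0, duration=41)
print(f"\nnitrogen balance (mg N/fish/d):")
print(f"  digestible intake {nb.digestible_n_intake:6.2f}")
print(f"  retained          {nb.retained_n:6.2f}")
print(f"  branchial/urinary {nb.branchial_urinary_n:6.2f}   (= DN - RN, identity)")
print(f"  N efficiency      {nb.n_efficiency:6.1f} %")

eb = energy_balance(feed_intake=0.76, diet_energy=20.0, adc_e=0.85,
                    bun=nb.branchial_urinary_n, body_e_initial=40.0,
                    body_e_final=260.0, duration=41,
                    retained_protein_energy=2.0, retained_fat_energy=1.5)
print(f"\nenergy balance (kJ/fish/d):")
print(f"  digestible      {eb.digestible_energy:6.2f}")
print(f"  metabolisable   {eb.metabolisable_energy:6.2f}   (DE minus ammonia-N losses)")
print(f"  retained        {eb.retained_energy:6.2f}")
print(f"  heat production {eb.heat_production:6.2f}   (= ME - RE)")
print(f"  maintenance     {eb.maintenance_energy:6.2f}   "
      "(ME minus protein/fat deposition costs at 50%/90% efficiency)")
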
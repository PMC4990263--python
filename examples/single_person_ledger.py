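"""Cost and QALY accounting for one hand-written screening history.

Builds a single person's yearly ledger — a FIT at 45, a colonoscopy with
two polypectomies at 55, early-cancer treatment at 60 — and prints the
discounted totals, showing exactly how the cost equation and the QALY sum
are applied.
"""

import crcsim

econ = crcsim.default_params().economics

ledger = crcsim.PersonLedger([
    crcsim.YearRecord(age=45, fit=True, utility=1.0),
    crcsim.YearRecord(age=55, colonoscopy=True, n_removed=2, utility=0.955),
    crcsim.YearRecord(age=60, early_treatment=True, utility=0.6),
])

cost = crcsim.cumulative_cost(ledger, econ)
qalys = crcsim.cumulative_qalys(ledger, econ)
print(f"discounted cost : {cost:8.2f} yuan")
print(f"discounted QALYs: {qalys:8.4f}")
print("\nThe cost is 9 at age 45, (290 + 150 + 2*500) * e^(-0.3) for the "
      "age-55 colonoscopy, and 4650 * e^(-0.45) for the resection; each "
      "year's utility is discounted the same way from age 45.")
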
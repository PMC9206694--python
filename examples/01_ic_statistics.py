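"""Information-component statistics for a single drug–event count vector.

Builds the contingency counts for a frequently reported drug–event pair,
computes the IC point estimate and its 95% credibility bounds, and shows
how the signal threshold (IC_025 > 0) reads off the result.
"""

from pvscreen import ContingencyCounts, ic_result

# 1722 reports mention both the drug and the event; the drug appears in
# 250 000 reports overall, the event in 3547, out of 20 million reports.
counts = ContingencyCounts(
    n_observed=1722, n_drug=250_000, n_effect=3547, n_total=20_000_000
)
result = ic_result(counts)

print(f"expected count E      : {counts.expected:8.2f}")
print(f"IC  (bits)            : {result.ic:8.3f}")
print(f"IC_025 / IC_975 (bits): {result.ic025:8.3f} / {result.ic975:8.3f}")
print(f"significant (IC_025>0): {result.significant}")

# The IC is the log2 shrunk observed/expected ratio: 2^IC estimates how many
# times more often the pair is reported than independence predicts; the
# credibility interval quantifies the Bayesian uncertainty of that ratio.
print(f"2^IC (reporting ratio): {2 ** result.ic:8.1f}")
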
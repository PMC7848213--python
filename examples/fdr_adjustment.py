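"""Benjamini–Hochberg adjustment of a four-test family of one-tailed
reveal-contrast p-values."""

from agrisk import fdr_adjust
from agrisk.config import make_fixtures

family = make_fixtures("worked_examples")["reveal_p_family"]
labels = list(family)
raw = [family[k] for k in labels]
adjusted = fdr_adjust(raw)

print("BH step-up over one four-test family:")
for label, p, p_adj in zip(labels, raw, adjusted):
    flag = "*" if p_adj < 0.05 else " "
    print(f"  {label:<18} p = {p:.4f} -> p_adj = {p_adj:.3f} {flag}")
print("\nOnly the $1,000 biosecurity contrast survives FDR control; the")
print("$1,000 infection contrast (raw p < 0.05) rises above 0.05 after")
print("adjustment, so it needs more sampling before claiming an effect.")
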
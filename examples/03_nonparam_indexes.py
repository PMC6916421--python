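"""Non-parametric circadian indexes for every recorded variable.

Runs one simulated DSPD subject through the index battery and prints the
phase markers (clock times), amplitude, stability, fragmentation and the
composite circadian function index, plus two worked examples computed
directly from published cohort means.
"""

import acmkit as ak

rec = ak.generate_subject(ak.phenotype_presets()["dspd"], days=7, seed=3)
epoched, summaries = ak.analyze_subject(rec)

print(f"{'variable':12s} {'L5h':>6s} {'M10h':>6s} {'RA':>6s} {'IS':>6s} {'IV':>6s} {'CFI':>6s}")
for name, s in summaries.items():
    l5h = f"{int(s.l5h // 60)}:{int(s.l5h % 60):02d}"
    m10h = f"{int(s.m10h // 60)}:{int(s.m10h % 60):02d}"
    print(f"{name:12s} {l5h:>6s} {m10h:>6s} {s.RA:6.3f} {s.IS:6.3f} {s.IV:6.3f} {s.CFI:6.3f}")

print("\nA DSPD subject shows TAP-L5h (mid-sleep) well after 5:27 and "
      "TAP-M10h (mid-activation) after 16:07.")

ra = ak.relative_amplitude(0.63, 0.13, "standard")
cfi = ak.circadian_function_index(0.75, 0.19, 0.98)
print(f"\nworked examples from published cohort means:")
print(f"  control TAP RA   = (0.63-0.13)/(0.63+0.13) = {ra:.2f}")
print(f"  control sleep CFI = (0.75 + (1-0.19/2) + 0.98)/3 = {cfi:.2f}")
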
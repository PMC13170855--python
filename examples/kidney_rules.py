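"""eGFR and KDIGO staging on hand-built seven-day creatinine windows."""

from trajaki import anomaly_aki_rule, compute_egfr, kdigo_stage

print("CKD-EPI 2021 race-free eGFR (mL/min/1.73 m^2):")
for scr, age, sex in [(0.9, 60, "male"), (0.7, 50, "female"), (2.0, 60, "male")]:
    print(f"  Scr {scr} mg/dL, {sex}, {age} y -> {compute_egfr(scr, age, sex):6.1f}")

print("\nKDIGO staging over a seven-step daily window (baseline = window min):")
windows = {
    "flat at 1.0":           [1.0] * 7,
    "48-h rise of 0.3":      [1.0] * 6 + [1.3],
    "gradual rise to 1.6x":  [1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6],
    "doubling":              [1.0, 1.1, 1.3, 1.5, 1.7, 1.9, 2.1],
}
for name, w in windows.items():
    st = kdigo_stage(w)
    print(f"  {name:22s} -> {st.stage:10s} (ratio {st.ratio_to_baseline:.2f}, "
          f"48-h rise {st.abs_rise_48h:.2f})")

print("\nComposite anomaly-detected AKI (rising final step AND score >= tau):")
for c_prev, c_last, s, tau in [(1.0, 1.2, 0.20, 0.13), (1.2, 1.2, 0.20, 0.13),
                               (1.0, 1.2, 0.05, 0.13)]:
    flags = anomaly_aki_rule(c_prev, c_last, s, tau)
    print(f"  c {c_prev}->{c_last}, s={s}, tau={tau}: anomaly_aki={flags.anomaly_aki}")
# A rise of exactly 0.3 mg/dL within 48 h or a 1.5x ratio gives stage 1; a
# 2.0x ratio gives stage >= 2. The composite rule needs both a strictly rising
# final step and a score at or above the fixed threshold.
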
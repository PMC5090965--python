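"""Estimate binding potential from simulated time-activity curves.

A cerebellum-like reference curve drives an SRTM target curve with known
parameters (R1 = 0.9, k2 = 0.25/min, BP = 1.5).  The SRTM basis-function fit
should recover all three parameters to within 1%, and the Logan reference
plot with the matched k2' should recover BP (= DVR - 1) to within 2%.
"""

from petlearn import KineticParams, estimate_k2prime, fit_srtm, logan_ref_bpnd
from petlearn.synth import ReferenceModelParams, simulate_reference_tac, simulate_target_tac

rp = ReferenceModelParams()          # difference-of-exponentials reference input
ref = simulate_reference_tac(rp)     # 41 frames over 90 min
truth = KineticParams(r1=0.9, k2=0.25, bp=1.5)
target = simulate_target_tac(rp, truth)

fit = fit_srtm(target, ref)
print(f"SRTM fit:   R1 = {fit.r1:.4f} (truth {truth.r1}), "
      f"k2 = {fit.k2:.4f}/min (truth {truth.k2}), BP = {fit.bp:.4f} (truth {truth.bp})")

k2p = estimate_k2prime(ref, [target])
print(f"k2' from signal-rich region: {k2p:.4f}/min (truth {truth.k2prime:.4f})")

logan = logan_ref_bpnd(target, ref, k2prime=k2p, t_star=30.0)
print(f"Logan fit:  DVR = {logan.dvr:.4f}, BPnd = {logan.bpnd:.4f}, "
      f"R^2 = {logan.r_squared:.6f}, frames used = {logan.n_points}")

print("\nBPnd is the specific-to-nondisplaceable binding ratio; agreement of"
      " the SRTM and Logan estimates with the generating values validates"
      " both estimators on this curve.")
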
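"""Belief-function basics: build two bodies of evidence, fuse them, decide.

Two sources assess a 3-class problem.  Source 1 backs class 1 but hedges
between classes 2 and 3; source 2 backs class 3 while allowing class 1.
Dempster's rule concentrates their joint mass, and the pignistic
transformation turns the fused belief into a probability for decision.
"""

from evicomb import Frame, combine, make_bba, pignistic

frame = Frame((1, 2, 3))
m1 = make_bba(frame, {(1,): 0.5, (2, 3): 0.3, (1, 2, 3): 0.2})
m2 = make_bba(frame, {(3,): 0.6, (1, 3): 0.4})

fused = combine(m1, m2)
print("fused BBA:")
for members, mass in fused.items():
    print(f"  m({members}) = {mass:.4f}")

betp = pignistic(fused)
print("pignistic probabilities:", [f"{p:.4f}" for p in betp.probs])
print("decision:", betp.argmax_class())
# The fused mass concentrates on class 3 (~0.60) with residual support for
# class 1; BetP splits the {1,3} mass equally, and class 3 wins.
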
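"""How fast do hands reach their contamination steady state?

One touch moves a binomial share of microbes each way between the hand and
the surface.  Repeated touching of the same surface drives the expected
hand load to the share q/(p+q) of the combined pool, and the deviation
shrinks by |1 - (p+q)| per touch.  This script prints the exact one-touch
distribution for a small pool and the number of touches needed to get
within 5% of the steady state for a range of transfer intensities.

Run:  python examples/steady_state.py
"""

import math

import numpy as np

from fecalflow import ContactParams, ContactPool, events_to_steady, expected_recursion, touch_pmf


def main() -> None:
    pool = ContactPool(N=4, M=10)  # 4 microbes on the hand patch, 10 on the surface
    params = ContactParams(p=0.75, q=0.02)  # typical: detachment >> attachment
    pmf = touch_pmf(pool, params)
    mean = float(np.arange(len(pmf)) @ pmf)
    print(f"one touch of a pool N={pool.N}, M={pool.M} at p={params.p}, q={params.q}:")
    print(f"  expected hand count afterwards: {mean:.3f} "
          f"(formula N(1-p)+Mq = {pool.N * 0.25 + pool.M * 0.02:.3f})")
    print(f"  P(hand ends empty) = {pmf[0]:.3f}, P(hand gains) = {pmf[pool.N + 1:].sum():.3f}")

    print("\nexpected loads over repeated touches (start: clean hand, loaded surface):")
    s, h = 1000.0, 0.0
    h_star = params.q / (params.p + params.q) * 1000.0
    for step in range(1, 6):
        s, h = expected_recursion(s, h, params, 1)
        print(f"  after {step} touches: hand {h:8.2f}   (steady state {h_star:.2f})")

    print("\ntouches to reach within 5% of steady state:")
    for label, p, q in [
        ("p+q = 1      ", 0.6, 0.40),
        ("p+q = 1-1/e  ", (1 - math.exp(-1)) * 0.75, (1 - math.exp(-1)) * 0.25),
        ("p+q = 0.5    ", 0.25, 0.25),
        ("p+q = 0.2    ", 0.15, 0.05),
    ]:
        n = events_to_steady(ContactParams(p, q), 0.05)
        print(f"  {label} (p={p:.3f}, q={q:.3f}): {n} touches")


if __name__ == "__main__":
    main()
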
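"""Enumerate channel-width families for the reference configuration.

The reference architecture (prune level 3, nested encoder blocks, fused
attention everywhere) is pinned up to its per-depth channel widths.  This
script enumerates width families (and the small structural knobs: nested
mid-width factor, attention reduction ratio) and reports those whose
trainable-parameter count and 112x112 forward FLOPs — under the package's
pinned MAC=2FLOP convention — match the published totals of 5.96 M
parameters and 25.74 GFLOPs.  The winning family is frozen into
``src/echoseg/configs/paper_reference.yaml``.

Run:  python scripts/match_reference.py [--verify]
"""

from __future__ import annotations

import argparse
import itertools

PARAM_TARGET = 5.96e6
FLOP_TARGET = 25.74e9
PARAM_TOL = 5e3          # printed precision: 5.96 M (two decimals)
FLOP_TOL = 0.26e9        # ~1% of the printed FLOP total
K_SPATIAL = 7
L = 3
H = W = 112


def vgg_params(cin, cout):
    return 9 * cin * cout + 9 * cout * cout + 4 * cout


def scbam_params(c, r):
    hid = c // r
    return 2 * c * hid + hid + c + (2 * K_SPATIAL ** 2 + 1)


def nested_params(cin, cout, mid, r):
    return ((cin * cout + cout) + vgg_params(cin, mid)
            + (4 * mid * cout + cout) + vgg_params(2 * cout, cout)
            + scbam_params(cout, r))


def model_params(w, r, mid_f):
    total = vgg_params(1, w[0]) + scbam_params(w[0], r)
    for i in range(1, L + 1):
        total += nested_params(w[i - 1], w[i], mid_f * w[i], r)
    for j in range(1, L + 1):
        for i in range(L - j + 1):
            total += 4 * w[i + 1] * w[i] + w[i]              # upsample
            total += vgg_params((j + 1) * w[i], w[i]) + scbam_params(w[i], r)
    total += L * (w[0] + 1)                                  # heads
    return total


def conv_flops(cin, cout, k, h, w, bias=False):
    f = 2 * k * k * cin * cout * h * w
    if bias:
        f += cout * h * w
    return f


def bn_flops(c, h, w):
    return 2 * c * h * w


def vgg_flops(cin, cout, h, w):
    return (conv_flops(cin, cout, 3, h, w) + bn_flops(cout, h, w)
            + conv_flops(cout, cout, 3, h, w) + bn_flops(cout, h, w))


def scbam_flops(c, r, h, w):
    hid = c // r
    mlp = (2 * c * hid + hid) + (2 * hid * c + c)
    return 2 * mlp + conv_flops(2, 1, K_SPATIAL, h, w, bias=True)


def up_flops(cin, cout, h_in, w_in):
    return 8 * cin * cout * h_in * w_in + 4 * cout * h_in * w_in


def nested_flops(cin, cout, mid, r, h, w):
    hh, ww = h // 2, w // 2
    return (conv_flops(cin, cout, 1, h, w, bias=True) + vgg_flops(cin, mid, hh, ww)
            + up_flops(mid, cout, hh, ww) + vgg_flops(2 * cout, cout, h, w)
            + scbam_flops(cout, r, h, w))


def model_flops(w, r, mid_f):
    total = vgg_flops(1, w[0], H, W) + scbam_flops(w[0], r, H, W)
    for i in range(1, L + 1):
        hi, wi = H >> i, W >> i
        total += nested_flops(w[i - 1], w[i], mid_f * w[i], r, hi, wi)
    for j in range(1, L + 1):
        for i in range(L - j + 1):
            hi, wi = H >> i, W >> i
            total += up_flops(w[i + 1], w[i], hi >> 1, wi >> 1)
            total += vgg_flops((j + 1) * w[i], w[i], hi, wi) + scbam_flops(w[i], r, hi, wi)
    for j in range(1, L + 1):
        total += conv_flops(w[0], 1, 1, H, W, bias=True)
    return total


def search(step=8, ratios=(16, 8), mid_factors=(1, 2)):
    hits = []
    for r, mid_f in itertools.product(ratios, mid_factors):
        ws0 = range(max(step, r), 129, step)
        for w0 in ws0:
            if w0 % r:
                continue
            for w1 in range(w0, 257, step):
                if w1 % r:
                    continue
                # prune on params lower bound cheaply
                for w2 in range(w1, 385, step):
                    if w2 % r:
                        continue
                    for w3 in range(w2, 513, step):
                        if w3 % r:
                            continue
                        w = (w0, w1, w2, w3)
                        p = model_params(w, r, mid_f)
                        if abs(p - PARAM_TARGET) > PARAM_TOL:
                            continue
                        f = model_flops(w, r, mid_f)
                        if abs(f - FLOP_TARGET) > FLOP_TOL:
                            continue
                        hits.append((w, r, mid_f, p, f))
    return hits


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--verify", action="store_true",
                    help="also build each hit and cross-check against the real counters")
    ap.add_argument("--step", type=int, default=8)
    args = ap.parse_args()

    hits = search(step=args.step)
    print(f"{len(hits)} width families match "
          f"{PARAM_TARGET/1e6:.2f} M / {FLOP_TARGET/1e9:.2f} G:")
    for w, r, mid_f, p, f in hits:
        print(f"  widths={w} r={r} mid_factor={mid_f}: "
              f"{p/1e6:.4f} M params, {f/1e9:.4f} GFLOPs")
    if args.verify and hits:
        from echoseg.attention import SCBAMConfig
        from echoseg.model import ModelConfig, build, count_flops, count_parameters
        for w, r, mid_f, p, f in hits:
            cfg = ModelConfig(channel_widths=tuple(w) + (2 * w[-1],), prune_level=3,
                              attention=SCBAMConfig(reduction_ratio=r),
                              nested_mid_factor=mid_f)
            m = build(cfg, seed=0)
            pp, ff = count_parameters(m), count_flops(m, (112, 112))
            ok = (pp == p) and (ff == f)
            print(f"  verify widths={w}: {pp/1e6:.4f} M, {ff/1e9:.4f} G "
                  f"{'OK' if ok else 'MISMATCH'}")


if __name__ == "__main__":
    main()
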
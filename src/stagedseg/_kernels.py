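"""JIT-compiled hot loops for the 3D network.

Direct-convolution kernels (forward / weight gradient) and a fused
instance-norm pair.  These avoid materializing im2col matrices, which keeps
per-step memory traffic near the size of the feature maps themselves.  The
pure-NumPy im2col path in ``_tensor`` remains the reference implementation
and the fallback when numba is unavailable; the two are cross-checked in
the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep of the env
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(fastmath=True)
def corr_fwd(xp, w, sd, sh, sw, out):
    """out[n,o] = sum_c corr(xp[n,c], w[o,c]) on the padded input."""
    n_batch, n_cin = xp.shape[0], xp.shape[1]
    n_out = w.shape[0]
    kd, kh, kw = w.shape[2], w.shape[3], w.shape[4]
    d_out, h_out, w_out = out.shape[2], out.shape[3], out.shape[4]
    for n in range(n_batch):
        for o in range(n_out):
            for d in range(d_out):
                for h in range(h_out):
                    row = out[n, o, d, h]
                    for x in range(w_out):
                        row[x] = 0.0
                    for c in range(n_cin):
                        for i in range(kd):
                            for j in range(kh):
                                src = xp[n, c, d * sd + i, h * sh + j]
                                for k in range(kw):
                                    wv = w[o, c, i, j, k]
                                    if sw == 1:
                                        for x in range(w_out):
                                            row[x] += wv * src[k + x]
                                    else:
                                        for x in range(w_out):
                                            row[x] += wv * src[x * sw + k]


@njit(fastmath=True)
def corr_dw(xp, dy, sd, sh, sw, dw):
    """Accumulate the weight gradient of corr_fwd into dw."""
    n_batch, n_cin = xp.shape[0], xp.shape[1]
    n_out = dw.shape[0]
    kd, kh, kw = dw.shape[2], dw.shape[3], dw.shape[4]
    d_out, h_out, w_out = dy.shape[2], dy.shape[3], dy.shape[4]
    for n in range(n_batch):
        for c in range(n_cin):
            dwl = np.zeros((n_out, kd, kh, kw), dtype=np.float32)
            for d in range(d_out):
                for h in range(h_out):
                    for i in range(kd):
                        for j in range(kh):
                            src = xp[n, c, d * sd + i, h * sh + j]
                            for o in range(n_out):
                                drow = dy[n, o, d, h]
                                for k in range(kw):
                                    acc = np.float32(0.0)
                                    if sw == 1:
                                        for x in range(w_out):
                                            acc += drow[x] * src[k + x]
                                    else:
                                        for x in range(w_out):
                                            acc += drow[x] * src[x * sw + k]
                                    dwl[o, i, j, k] += acc
            for o in range(n_out):
                for i in range(kd):
                    for j in range(kh):
                        for k in range(kw):
                            dw[o, c, i, j, k] += dwl[o, i, j, k]


@njit(fastmath=True)
def corr_fwd3(xp, w, out):
    """corr_fwd specialized for 3x3x3 kernels at stride 1 (the common case)."""
    n_batch, n_cin = xp.shape[0], xp.shape[1]
    n_out = out.shape[1]
    d_out, h_out, w_out = out.shape[2], out.shape[3], out.shape[4]
    for n in range(n_batch):
        for o in range(n_out):
            for d in range(d_out):
                for h in range(h_out):
                    row = out[n, o, d, h]
                    for x in range(w_out):
                        row[x] = 0.0
                    for c in range(n_cin):
                        for i in range(3):
                            for j in range(3):
                                src = xp[n, c, d + i, h + j]
                                w0 = w[o, c, i, j, 0]
                                w1 = w[o, c, i, j, 1]
                                w2 = w[o, c, i, j, 2]
                                for x in range(w_out):
                                    row[x] += w0 * src[x] + w1 * src[x + 1] + w2 * src[x + 2]


@njit(fastmath=True)
def corr_dw3(xp, dy, dw):
    """corr_dw specialized for 3x3x3 kernels at stride 1."""
    n_batch, n_cin = xp.shape[0], xp.shape[1]
    n_out = dw.shape[0]
    d_out, h_out, w_out = dy.shape[2], dy.shape[3], dy.shape[4]
    for n in range(n_batch):
        for c in range(n_cin):
            dwl = np.zeros((n_out, 3, 3, 3), dtype=np.float32)
            for d in range(d_out):
                for h in range(h_out):
                    for i in range(3):
                        for j in range(3):
                            src = xp[n, c, d + i, h + j]
                            for o in range(n_out):
                                drow = dy[n, o, d, h]
                                a0 = np.float32(0.0)
                                a1 = np.float32(0.0)
                                a2 = np.float32(0.0)
                                for x in range(w_out):
                                    g = drow[x]
                                    a0 += g * src[x]
                                    a1 += g * src[x + 1]
                                    a2 += g * src[x + 2]
                                dwl[o, i, j, 0] += a0
                                dwl[o, i, j, 1] += a1
                                dwl[o, i, j, 2] += a2
            for o in range(n_out):
                for i in range(3):
                    for j in range(3):
                        for k in range(3):
                            dw[o, c, i, j, k] += dwl[o, i, j, k]


@njit(fastmath=True)
def leaky_fwd(x, alpha, y):
    n = x.size
    xf = x.reshape(n)
    yf = y.reshape(n)
    for t in range(n):
        v = xf[t]
        yf[t] = v if v > 0.0 else alpha * v


@njit(fastmath=True)
def leaky_bwd(y, dy, alpha, dx):
    n = y.size
    yf = y.reshape(n)
    df = dy.reshape(n)
    of = dx.reshape(n)
    for t in range(n):
        g = df[t]
        of[t] = g if yf[t] > 0.0 else alpha * g


@njit(fastmath=True)
def innorm_fwd(x, gamma, beta, eps, y, mu, inv):
    """Instance norm forward; writes y and the per-(n,c) mean / inverse sd."""
    n_batch, n_ch = x.shape[0], x.shape[1]
    m = x.shape[2] * x.shape[3] * x.shape[4]
    for n in range(n_batch):
        for c in range(n_ch):
            flat = x[n, c].reshape(m)
            s1 = np.float32(0.0)
            s2 = np.float32(0.0)
            for t in range(m):
                v = flat[t]
                s1 += v
                s2 += v * v
            mean = s1 / m
            var = s2 / m - mean * mean
            if var < 0.0:
                var = 0.0
            istd = np.float32(1.0) / np.sqrt(var + eps)
            mu[n, c] = mean
            inv[n, c] = istd
            a = gamma[c] * istd
            b = beta[c] - mean * a
            yflat = y[n, c].reshape(m)
            for t in range(m):
                yflat[t] = a * flat[t] + b


@njit(fastmath=True)
def innorm_bwd(x, dy, gamma, mu, inv, dx, dgamma, dbeta):
    """Instance norm backward; xhat is recomputed from x, mu, inv."""
    n_batch, n_ch = x.shape[0], x.shape[1]
    m = x.shape[2] * x.shape[3] * x.shape[4]
    for n in range(n_batch):
        for c in range(n_ch):
            flat = x[n, c].reshape(m)
            dflat = dy[n, c].reshape(m)
            mean = mu[n, c]
            istd = inv[n, c]
            s_dy = np.float32(0.0)
            s_dyx = np.float32(0.0)
            for t in range(m):
                xh = (flat[t] - mean) * istd
                s_dy += dflat[t]
                s_dyx += dflat[t] * xh
            dgamma[c] += s_dyx
            dbeta[c] += s_dy
            g = gamma[c]
            m1 = s_dy / m
            m2 = s_dyx / m
            out = dx[n, c].reshape(m)
            for t in range(m):
                xh = (flat[t] - mean) * istd
                out[t] = (g * (dflat[t] - m1) - g * xh * m2) * istd
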
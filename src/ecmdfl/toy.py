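"""Scalar hard-spring worked example of dual-faceted linearization.

The system couples a hard spring to a damper with negligible mass,
F - D dx/dt = 0 with F = a x + b x^3, i.e. dx/dt = (a/D) x + (b/D) x^3.
The state equation expressed in the force variable F is nonlinear, but
regressing dF/dt on (x, F) along a trajectory gives a linear augmented
model

    dx/dt = W_F F,        dF/dt ~= S_x x + S_F F,   W_F = 1/D,

whose x-channel is exact by construction.  This module also provides the
first-order Taylor and trajectory-piecewise-linear (TPWL) baselines and an
independent Runge-Kutta reference integrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ToySpringSystem"]


@dataclass
class ToySpringSystem:
    """Hard spring driving a damper: D dx/dt = a x + b x^3."""

    a: float = 1.0
    b: float = 1.0
    D: float = 1.0

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("damping D must be positive")

    @property
    def W_F(self) -> float:
        return 1.0 / self.D

    def force(self, x):
        return self.a * x + self.b * x**3

    def dxdt(self, x):
        return self.force(x) / self.D

    # ------------------------------------------------------------------ #
    def simulate_rk4(self, x0: float, ts: np.ndarray) -> np.ndarray:
        """Classical fixed-step RK4 reference trajectory of the exact ODE."""
        ts = np.asarray(ts, dtype=float)
        xs = np.empty_like(ts)
        xs[0] = x0
        for n in range(len(ts) - 1):
            h = ts[n + 1] - ts[n]
            x = xs[n]
            k1 = self.dxdt(x)
            k2 = self.dxdt(x + 0.5 * h * k1)
            k3 = self.dxdt(x + 0.5 * h * k2)
            k4 = self.dxdt(x + h * k3)
            xs[n + 1] = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        return xs

    # ------------------------------------------------------------------ #
    def df_fit(self, xs: np.ndarray, ts: np.ndarray):
        """Least-squares fit of dF/dt ~= S_x x + S_F F along a trajectory.

        Returns (S_x, S_F).  Raises on a degenerate (constant) trajectory.
        dF/dt samples come from the chain rule dF/dt = (a + 3 b x^2) dx/dt
        with the exact dx/dt = F/D, so the fit error reflects only the
        linear-regression approximation, not differencing noise.
        """
        xs = np.asarray(xs, dtype=float)
        ts = np.asarray(ts, dtype=float)
        if np.ptp(xs) < 1e-14:
            raise ValueError("degenerate trajectory: regressor is rank deficient")
        Fs = self.force(xs)
        dFdt = (self.a + 3 * self.b * xs**2) * (Fs / self.D)
        A = np.column_stack([xs, Fs])
        sol, *_ = np.linalg.lstsq(A, dFdt, rcond=None)
        return float(sol[0]), float(sol[1])

    def simulate_df(self, x0: float, ts: np.ndarray, S_x: float, S_F: float) -> np.ndarray:
        """Augmented linear simulation: exact x-channel + regressed F-channel.

        Integrates the 2x2 linear system d[x, F]/dt = M [x, F] with the
        matrix exponential per step (the augmented model is linear, so this
        is its exact solution).  Returns x(t).
        """
        from scipy.linalg import expm

        M = np.array([[0.0, self.W_F], [S_x, S_F]])
        ts = np.asarray(ts, dtype=float)
        state = np.array([x0, self.force(x0)])
        xs = np.empty_like(ts)
        xs[0] = x0
        steps = np.diff(ts)
        if np.allclose(steps, steps[0]):
            Phi = expm(M * steps[0])
            for n in range(len(ts) - 1):
                state = Phi @ state
                xs[n + 1] = state[0]
        else:
            for n in range(len(ts) - 1):
                state = expm(M * steps[n]) @ state
                xs[n + 1] = state[0]
        return xs

    # ------------------------------------------------------------------ #
    def simulate_taylor(self, x0: float, ts: np.ndarray, x_ref: float | None = None) -> np.ndarray:
        """First-order Taylor baseline about ``x_ref`` (default: x0).

        F(x) ~= F(x_ref) + J (x - x_ref), J = a + 3 b x_ref^2; the resulting
        affine ODE is integrated exactly.
        """
        if x_ref is None:
            x_ref = x0
        ts = np.asarray(ts, dtype=float)
        J = self.a + 3 * self.b * x_ref**2
        c = self.force(x_ref) - J * x_ref
        # dx/dt = (J x + c)/D : affine ODE, solved exactly
        lam = J / self.D
        if J != 0:
            xstar = -c / J
            xs = xstar + (x0 - xstar) * np.exp(lam * (ts - ts[0]))
        else:
            xs = x0 + (c / self.D) * (ts - ts[0])
        return xs

    def simulate_tpwl(
        self, x0: float, ts: np.ndarray, train_xs: np.ndarray,
        kappa: int = 100, bandwidth: float | None = None,
    ) -> np.ndarray:
        """TPWL baseline: kernel-weighted local linearizations along a trajectory.

        ``kappa`` linearization points are taken uniformly along the training
        trajectory; at each step the vector field is the normalised-Gaussian-
        weighted combination of the local affine models.  With kappa = 1 this
        reduces to the Taylor baseline about the single point.
        """
        train_xs = np.asarray(train_xs, dtype=float)
        idx = np.unique(np.linspace(0, len(train_xs) - 1, kappa).round().astype(int))
        pts = train_xs[idx]
        Js = self.a + 3 * self.b * pts**2
        Fs = self.force(pts)
        if bandwidth is None:
            span = max(np.ptp(pts), 1e-12)
            bandwidth = span / max(len(pts), 2)

        def field(x):
            w = np.exp(-0.5 * ((x - pts) / bandwidth) ** 2)
            s = w.sum()
            if s < 1e-300:
                j = int(np.argmin(np.abs(x - pts)))
                w = np.zeros_like(w)
                w[j] = 1.0
                s = 1.0
            w = w / s
            Fhat = np.sum(w * (Fs + Js * (x - pts)))
            return Fhat / self.D

        ts = np.asarray(ts, dtype=float)
        xs = np.empty_like(ts)
        xs[0] = x0
        for n in range(len(ts) - 1):
            h = ts[n + 1] - ts[n]
            x = xs[n]
            k1 = field(x)
            k2 = field(x + 0.5 * h * k1)
            k3 = field(x + 0.5 * h * k2)
            k4 = field(x + h * k3)
            xs[n + 1] = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        return xs
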
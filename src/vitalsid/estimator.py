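"""Per-patient identity verifier built on the trainable rule-fact network.

:class:`GDESVerifier` is a scikit-learn style, one-class estimator: ``fit``
consumes a single patient's normalized vital-sign stream (an ``(n, 4)``
array in the canonical channel order heart rate, end-tidal CO2, respiratory
rate, blood pressure, all values in [0, 1]) and produces a trained rule-fact
network plus a *target value* — the network output for a baseline "present"
evaluation.  New samples are scored by the absolute deviation of their
network output from that target: the patient the profile was trained on
should deviate least.

Four baseline (PR) recipes are supported, selected by ``pr_approach``:

``fixed_single``
    present with the start (blood-pressure) fact at ``default_fact_value``;
    the other input facts keep their last training values.
``actual_last_bp``
    present with the last training row's blood-pressure value, producing a
    natural output from the trained network.
``fixed_all_facts``
    set all four input facts to ``default_fact_value`` first, then present
    with that value.
``averaged_facts``
    set each input fact to its training-period mean, then present with the
    mean blood-pressure value.

Values cross the engine boundary in the command protocol's three-decimal
fixed-point form, so inputs are quantized to three decimals before use; a
fitted profile can emit the exact SF/TR/PR command script it executed
(``record_script=True``), and replaying that script on an identically built
network reproduces the fitted weights bit for bit.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .commands import Command, format_command, quantize
from .network import CHANNELS, build_network

__all__ = ["GDESVerifier", "PR_APPROACHES"]

PR_APPROACHES = (
    "fixed_single",
    "actual_last_bp",
    "fixed_all_facts",
    "averaged_facts",
)


class GDESVerifier(BaseEstimator):
    """Vital-sign identity verifier using a gradient-descent-trained
    rule-fact expert system.

    Parameters
    ----------
    design_id : {1, 2, 3}, default=3
        Which of the three fixed seven-fact/three-rule topologies to use
        (they differ in how the four vitals are paired at the first layer).
    velocity : float, default=0.1
        Learning-rate scalar for the per-row training update.  Values in
        (0, 1] guarantee per-step error non-increase.
    default_fact_value : float, default=0.5
        Initial value of every fact at construction, and the fixed input
        value used by the ``fixed_single`` / ``fixed_all_facts`` baselines.
    pr_approach : str, default="fixed_single"
        Baseline recipe producing the target value (see module docstring).
    train_target : float, default=0.5
        Output value the training updates drive toward; the midpoint of the
        valid range, so other patients can deviate in either direction.
    margin : float, default=0.025
        Deviation threshold used by :meth:`predict` and :meth:`verify`.
    stride : int, default=1
        Train on every ``stride``-th row (1 = every row).
    reset_value : float, default=0.5
        Value the intermediate facts are reset to between scoring runs.
    record_script : bool, default=False
        Record every SF/TR/PR command executed into ``script_``.
    random_state : int, Generator or None
        Seeds the GUID assignment of the freshly built network (affects only
        identifier strings, never numerics).

    Attributes
    ----------
    network_ : RuleFactNetwork
        The trained network.
    target_value_ : float
        Baseline output all scored samples are compared against.
    train_means_ : ndarray of shape (4,)
        Per-channel means of the (quantized) training rows.
    last_row_ : ndarray of shape (4,)
        Last (quantized) training row.
    script_ : list of str
        Executed command script (only when ``record_script=True``).
    """

    def __init__(
        self,
        design_id: int = 3,
        velocity: float = 0.1,
        default_fact_value: float = 0.5,
        pr_approach: str = "fixed_single",
        train_target: float = 0.5,
        margin: float = 0.025,
        stride: int = 1,
        reset_value: float = 0.5,
        record_script: bool = False,
        random_state=None,
    ) -> None:
        self.design_id = design_id
        self.velocity = velocity
        self.default_fact_value = default_fact_value
        self.pr_approach = pr_approach
        self.train_target = train_target
        self.margin = margin
        self.stride = stride
        self.reset_value = reset_value
        self.record_script = record_script
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _validate_X(self, X) -> np.ndarray:
        X = check_array(X, dtype=np.float64, ensure_min_features=4)
        if X.shape[1] != 4:
            raise ValueError(
                f"expected 4 vital-sign channels {CHANNELS}, got {X.shape[1]}"
            )
        if X.min() < 0.0 or X.max() > 1.0:
            raise ValueError("normalized vitals must lie in [0, 1]")
        return X

    def _rng(self):
        if isinstance(self.random_state, np.random.Generator):
            return self.random_state
        if self.random_state is None:
            return None
        return np.random.default_rng(self.random_state)

    def _record(self, kind: str, guids: tuple[str, ...], value: float) -> None:
        if self.record_script:
            self.script_.append(format_command(Command(kind, guids, value)))

    def _sf(self, guid: str, value: float) -> None:
        self.network_.set_fact(guid, value)
        self._record("SF", (guid,), value)

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None) -> "GDESVerifier":
        """Train the per-patient profile on a normalized vitals stream."""
        if self.pr_approach not in PR_APPROACHES:
            raise ValueError(
                f"unknown pr_approach {self.pr_approach!r}; "
                f"expected one of {PR_APPROACHES}"
            )
        if not (0 < self.velocity <= 1):
            raise ValueError("velocity must lie in (0, 1]")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        X = self._validate_X(X)
        rows = np.vectorize(quantize)(X[:: self.stride])
        if len(rows) == 0:
            raise ValueError("no training rows after striding")
        self.script_: list[str] = []
        net = build_network(self.design_id, self.default_fact_value, self._rng())
        self.network_ = net
        self._train_rows(rows)
        self.train_means_ = rows.mean(axis=0)
        self.last_row_ = rows[-1]
        self.target_value_ = self._baseline()
        self.n_features_in_ = 4
        return self

    def _train_rows(self, rows: np.ndarray) -> None:
        """Tight training loop specialised to the fixed two-level topology.

        Numerically identical to issuing four SF commands plus one TR
        (generic :meth:`RuleFactNetwork.train_step`) per row; the equivalence
        is asserted by the test suite.
        """
        net = self.network_
        rule_c = net._order[-1]
        by_output = {r.output_fact_guid: r for r in net.rules.values()}
        rule_a = by_output[rule_c.input_fact_guids[0]]
        rule_b = by_output[rule_c.input_fact_guids[1]]
        col = {net.channel_map[ch]: j for j, ch in enumerate(CHANNELS)}
        ia1, ia2 = (col[g] for g in rule_a.input_fact_guids)
        ib1, ib2 = (col[g] for g in rule_b.input_fact_guids)
        wa1, wa2 = rule_a.weights
        wb1, wb2 = rule_b.weights
        wc1, wc2 = rule_c.weights
        target = self.train_target
        vel = self.velocity
        bp_guid = net.channel_map["blood_pressure"]
        out_guid = net.output_fact_guid
        record = self.record_script
        guid_by_col = [net.channel_map[ch] for ch in CHANNELS]
        for row in rows:
            if record:
                for g, v in zip(guid_by_col, row):
                    self._record("SF", (g,), v)
                self._record("TR", (bp_guid, out_guid), row[3])
            a = wa1 * row[ia1] + wa2 * row[ia2]
            b = wb1 * row[ib1] + wb2 * row[ib2]
            out = wc1 * a + wc2 * b
            error = target - out
            if error == 0.0:
                continue
            total = wc1 + wc2 + 1.0
            # first-layer rule A (contribution = downstream weight wc1)
            v1, v2 = row[ia1], row[ia2]
            if v1 != v2:
                delta = vel * (error * (wc1 / total))
                w = wa1 + delta if v1 > v2 else wa1 - delta
                w = 0.0 if w < 0.0 else (1.0 if w > 1.0 else w)
                wa1, wa2 = w, 1.0 - w
            # first-layer rule B (contribution wc2)
            v1, v2 = row[ib1], row[ib2]
            if v1 != v2:
                delta = vel * (error * (wc2 / total))
                w = wb1 + delta if v1 > v2 else wb1 - delta
                w = 0.0 if w < 0.0 else (1.0 if w > 1.0 else w)
                wb1, wb2 = w, 1.0 - w
            # final rule (contribution 1); inputs are the pre-update a, b
            if a != b:
                delta = vel * (error * (1.0 / total))
                w = wc1 + delta if a > b else wc1 - delta
                w = 0.0 if w < 0.0 else (1.0 if w > 1.0 else w)
                wc1, wc2 = w, 1.0 - w
        rule_a.weights[:] = [wa1, wa2]
        rule_b.weights[:] = [wb1, wb2]
        rule_c.weights[:] = [wc1, wc2]
        # Leave fact state as the generic command stream would: inputs at the
        # last row's values, intermediates/output re-evaluated under the
        # final weights.
        last = rows[-1]
        for g, v in zip(guid_by_col, last):
            net.set_fact(g, v)
        net.evaluate()

    def _baseline(self) -> float:
        net = self.network_
        bp = net.channel_map["blood_pressure"]
        out = net.output_fact_guid
        approach = self.pr_approach
        if approach == "fixed_single":
            value = quantize(self.default_fact_value)
        elif approach == "actual_last_bp":
            value = self.last_row_[3]
        elif approach == "fixed_all_facts":
            value = quantize(self.default_fact_value)
            for ch in CHANNELS:
                self._sf(net.channel_map[ch], value)
        else:  # averaged_facts
            for ch, m in zip(CHANNELS, self.train_means_):
                self._sf(net.channel_map[ch], quantize(m))
            value = quantize(self.train_means_[3])
        result = net.present(bp, value)
        self._record("PR", (bp, out), value)
        return result

    # -- scoring -----------------------------------------------------------

    def outputs(self, X) -> np.ndarray:
        """Raw network outputs for each row.

        Each row is applied as four SF commands plus a PR from the
        blood-pressure fact; intermediate facts are reset to ``reset_value``
        after every run.
        """
        check_is_fitted(self, "target_value_")
        X = self._validate_X(X)
        net = self.network_
        bp = net.channel_map["blood_pressure"]
        out_guid = net.output_fact_guid
        outs = np.empty(len(X))
        for i, raw in enumerate(X):
            row = [quantize(v) for v in raw]
            for ch, v in zip(CHANNELS, row):
                self._sf(net.channel_map[ch], v)
            outs[i] = net.present(bp, row[3])
            self._record("PR", (bp, out_guid), row[3])
            for f in net.facts.values():
                if f.kind == "intermediate":
                    self._sf(f.guid, self.reset_value)
        return outs

    def deviations(self, X) -> np.ndarray:
        """Per-row absolute deviation of the network output from the
        fitted target value."""
        return np.abs(self.outputs(X) - self.target_value_)

    def average_deviation(self, X) -> float:
        return float(self.deviations(X).mean())

    def decision_function(self, X) -> np.ndarray:
        """Signed margin: positive where a row is consistent with the
        profile at the configured margin."""
        return self.margin - self.deviations(X)

    def predict(self, X) -> np.ndarray:
        """Boolean per-row consistency flags at the configured margin."""
        return self.decision_function(X) > 0

    def verify(self, X) -> str:
        """Sample-level verdict: ``consistent`` when the average deviation is
        below the margin, else ``alert``."""
        return (
            "consistent" if self.average_deviation(X) < self.margin else "alert"
        )
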
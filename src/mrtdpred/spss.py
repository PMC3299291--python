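"""The published scoring-code dialect: verbatim oracle, interpreter, exporter.

The published 6-2-1 network ships as a block of SPSS-style ``COMPUTE``
statements.  This module keeps that block verbatim
(:data:`PUBLISHED_NETWORK_CODE`), provides a tiny interpreter that
evaluates such blocks statement by statement
(:func:`evaluate_dialect`), and can emit any :class:`~mrtdpred.network.NetworkSpec`
back into the same dialect (:func:`export_dialect`).

The interpreter deliberately performs no algebraic simplification: it is
the independent, statement-by-statement oracle against which the folded
:func:`~mrtdpred.network.predict_network` evaluator is proven equivalent.
"""

from __future__ import annotations

import math
import re

import numpy as np

from .datasets import DESCRIPTOR_COLUMNS, descriptor_matrix
from .network import NetworkSpec

#: canonical column -> dialect variable name
DIALECT_NAMES = {
    "oxid_hl": "OxidHL",
    "p_bd": "Pr_BD_",
    "log_bio_hl": "LogBioHL",
    "alogp": "ALogP",
    "asol": "Sol",
    "mw": "MW",
}

#: The published 6-2-1 network scoring code, verbatim (including the
#: typeset Unicode minus signs, which the interpreter normalizes).
PUBLISHED_NETWORK_CODE = """\
COMPUTE Var1 = ((OxidHL * (−0.543086558961242)) + 3.63976611815824)
 + ((Pr_BD_ * (−5.67413921537257)) + 2.81153598121711)
+ ((LogBioHL * (0.40828801067156)) + 0.747514104338025)
+ ((ALogP * (−0.848110602763694)) + 1.43330691867064)
 + ((Sol * (−2.55399028293542E−02)) + 0.517313285798853)
+ ((MW * (1.40343495376914E−02)) − 5.94322423917294)
+ 3.86733992096867.
COMPUTE Var2 = ((OxidHL * (8.23491975851945E−02)) - 0.551904322215974)
+ ((Pr_BD_ * (3.12529587401663)) - 1.54858410557524)
+ ((LogBioHL * (0.431493610228662)) + 0.790000076287146)
+ ((ALogP * (−0.04107624611641)) + 6.94188559367329E−02)
+ ((Sol * (4.12997852313067E−02)) − 0.836531279838639)
+ ((MW * (1.05078568602304E−03)) − 0.444983569959981)
+ 9.28741349960935E-02.
COMPUTE Var3 = −0.535249116383622.
Execute.
COMPUTE Var1 = 0.108990429907616 * Var1.
COMPUTE Var2 = 1.44376333322051 * (Exp(Var2) − Exp(-Var2)) / (Exp(Var2) + Exp(−Var2)).
COMPUTE Var3 = Var3.
Execute.
COMPUTE Tiberius_MRTD = ((((Var1 + Var2 + Var3)/2.0) + 0.5) * 199.9625) + 0.0375.
Execute.
"""

_STATEMENT = re.compile(
    r"COMPUTE\s+(\w+)\s*=\s*(.*?)\.(?=\s*(?:COMPUTE|Execute|$))", re.DOTALL
)
_ALLOWED = re.compile(r"^[\w\s+\-*/().eE]+$")


def _parse(code: str) -> list[tuple[str, str]]:
    code = code.replace("−", "-")
    statements = _STATEMENT.findall(code)
    if not statements:
        raise ValueError("no COMPUTE statements found")
    return [(name, " ".join(expr.split())) for name, expr in statements]


def evaluate_dialect(code: str, descriptors) -> float | np.ndarray:
    """Execute a COMPUTE block for descriptor input, statement by statement.

    The value of the variable assigned by the final ``COMPUTE`` statement
    is returned.  Accepts the same descriptor forms as the model
    evaluators (dataset frame, mapping, or array in canonical order);
    a single row yields a scalar.
    """
    A = descriptor_matrix(descriptors)
    statements = _parse(code)
    results = np.empty(A.shape[0])
    for i, row in enumerate(A):
        env: dict[str, float] = {
            DIALECT_NAMES[c]: float(v) for c, v in zip(DESCRIPTOR_COLUMNS, row)
        }
        env["Exp"] = math.exp
        for name, expr in statements:
            if not _ALLOWED.match(expr):
                raise ValueError(f"unsupported token in expression: {expr!r}")
            env[name] = eval(expr, {"__builtins__": {}}, env)  # noqa: S307
        results[i] = env[statements[-1][0]]
    return float(results[0]) if A.shape[0] == 1 else results


def verbatim_network_prediction(descriptors) -> float | np.ndarray:
    """MRTD from the published code block, with no constant folding.

    Test oracle for the folded network evaluator.
    """
    return evaluate_dialect(PUBLISHED_NETWORK_CODE, descriptors)


def export_dialect(net: NetworkSpec, output_name: str = "Predicted_MRTD") -> str:
    """Emit a network as COMPUTE statements in the published dialect.

    Re-parsing the text with :func:`evaluate_dialect` reproduces
    ``net.predict`` to within floating-point round-trip accuracy
    (constants are written with ``repr`` precision).
    """
    if not net.hidden:
        raise ValueError("network has no hidden units")
    lines = []
    var_names = [f"Var{i + 1}" for i in range(len(net.hidden) + len(net.constants))]

    for var, unit in zip(var_names, net.hidden):
        terms = [
            f"(({DIALECT_NAMES[c]} * ({float(w)!r})) + 0)"
            for c, w in zip(DESCRIPTOR_COLUMNS, unit.weights)
        ]
        terms.append(f"{float(unit.bias)!r}")
        lines.append(f"COMPUTE {var} = " + "\n + ".join(terms) + ".")
    for var, const in zip(var_names[len(net.hidden) :], net.constants):
        lines.append(f"COMPUTE {var} = {float(const)!r}.")
    lines.append("Execute.")

    for var, unit in zip(var_names, net.hidden):
        if unit.activation == "tanh":
            lines.append(
                f"COMPUTE {var} = {float(unit.post_scale)!r} * "
                f"(Exp({var}) - Exp(-{var})) / (Exp({var}) + Exp(-{var}))."
            )
        else:
            lines.append(f"COMPUTE {var} = {float(unit.post_scale)!r} * {var}.")
    for var in var_names[len(net.hidden) :]:
        lines.append(f"COMPUTE {var} = {var}.")
    lines.append("Execute.")

    total = " + ".join(var_names)
    lines.append(
        f"COMPUTE {output_name} = (((({total})/{float(net.divisor)!r}) + 0.5) * "
        f"{float(net.out_range)!r}) + {float(net.out_offset)!r}."
    )
    lines.append("Execute.")
    return "\n".join(lines) + "\n"
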
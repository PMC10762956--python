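"""String-level SMILES handling.

Canonicalization and non-canonical enumeration are delegated to RDKit; what
this module adds is a deterministic atom-level tokenizer with a reserved
``<missing>`` token, and the exact prompt-completion JSONL format used to
fine-tune text classifiers on SMILES.

The tokenizer is intentionally not a learned byte-pair encoder: token
boundaries coincide with the chemical lexical units of SMILES (one token per
atom, bond symbol, ring-closure digit or parenthesis), so that replacing one
atom is a single-token edit.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem
from rdkit.Chem import MolToRandomSmilesVect
from rdkit import RDLogger

from .errors import (
    EnumerationExhaustedError,
    JsonlFormatError,
    SmilesParseError,
    TokenizationError,
)

RDLogger.DisableLog("rdApp.*")

MISSING_TOKEN = "<missing>"

#: Two-letter element symbols that may appear outside brackets (the organic
#: subset plus the bare symbols used by the mutation probe).
_TWO_LETTER = ("Cl", "Br", "Si", "Se", "As")

_TOKEN_RE = re.compile(
    r"<missing>"
    r"|\[[^\[\]]*\]"          # bracket atom, one token
    r"|%\d{2}"                # two-digit ring closure
    r"|Cl|Br|Si|Se|As"        # two-letter elements, never split
    r"|[BCNOPSFI]"            # aliphatic organic-subset atoms
    r"|[bcnops]"              # aromatic organic-subset atoms
    r"|\*"                    # wildcard atom
    r"|\d"                    # ring closure digit
    r"|[-=#$:/\\().+~@]"      # bonds, branches, stereo marks
)

_ATOM_SINGLE = set("BCNOPSFIbcnops*")


def is_atom_token(token: str) -> bool:
    """True for tokens that denote an atom (``<missing>`` is not an atom)."""
    return (
        token.startswith("[")
        or token in _TWO_LETTER
        or (len(token) == 1 and token in _ATOM_SINGLE)
    )


@dataclass(frozen=True)
class TokenSequence:
    """An ordered sequence of SMILES tokens.

    Concatenating ``tokens`` reproduces the source text exactly, so a
    single-token replacement yields a string differing from the parent in
    exactly one token span.
    """

    tokens: tuple[str, ...]

    @property
    def text(self) -> str:
        return "".join(self.tokens)

    def atom_positions(self) -> list[int]:
        """Indices into ``tokens`` of the atom tokens, in reading order."""
        return [i for i, t in enumerate(self.tokens) if is_atom_token(t)]

    def replaced(self, positions: Iterable[int], replacement) -> "TokenSequence":
        """Return a copy with tokens at ``positions`` substituted.

        ``replacement`` is either a single string applied everywhere or a
        mapping position -> string.
        """
        toks = list(self.tokens)
        if isinstance(replacement, str):
            for p in positions:
                toks[p] = replacement
        else:
            for p in positions:
                toks[p] = replacement[p]
        return TokenSequence(tuple(toks))

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize(text: str, strict: bool = True) -> TokenSequence:
    """Split SMILES text (possibly containing ``<missing>``) into tokens.

    With ``strict=False`` unrecognized characters become single-character
    tokens instead of raising, which is what classifier backends use to
    accept arbitrary perturbed text.
    """
    tokens: list[str] = []
    pos = 0
    n = len(text)
    while pos < n:
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            ch = text[pos]
            if strict:
                if ch == "[":
                    raise TokenizationError(
                        f"unterminated bracket atom at position {pos} in {text!r}"
                    )
                raise TokenizationError(
                    f"unrecognized character {ch!r} at position {pos} in {text!r}"
                )
            tokens.append(ch)
            pos += 1
            continue
        tokens.append(m.group(0))
        pos = m.end()
    return TokenSequence(tuple(tokens))


def detokenize(seq: TokenSequence | Sequence[str]) -> str:
    """Inverse of :func:`tokenize`: concatenation of the tokens."""
    if isinstance(seq, TokenSequence):
        return seq.text
    return "".join(seq)


def mol_from_smiles(smiles: str, context: str = "") -> Chem.Mol:
    """Parse SMILES or raise :class:`SmilesParseError` naming the string.

    Atom indices of the returned molecule follow the order in which atoms
    appear in the input string, which is what lets token positions and atom
    indices be aligned by rank.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, context)
    return mol


def canonicalize(smiles: str) -> str:
    """Map any valid SMILES of a molecule to its unique canonical form."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def enumerate_noncanonical(
    smiles: str, n: int, seed: int, retry_factor: int = 100
) -> list[str]:
    """Generate ``n`` distinct valid non-canonical renderings of a molecule.

    Renderings are produced by randomized atom-order traversal; duplicates
    and the canonical string itself are rejected. Raises
    :class:`EnumerationExhaustedError` when the molecule admits too few
    distinct renderings within the retry budget (``retry_factor * n``
    draws), e.g. for single-heavy-atom molecules.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mol = mol_from_smiles(smiles)
    canonical = Chem.MolToSmiles(mol)
    # RDKit treats a zero/negative seed as "randomize"; keep it positive.
    rdkit_seed = int(seed) % (2**31 - 2) + 1
    budget = retry_factor * n
    out: list[str] = []
    seen = {canonical}
    for s in MolToRandomSmilesVect(mol, budget, randomSeed=rdkit_seed):
        if s in seen:
            continue
        seen.add(s)
        out.append(s)
        if len(out) == n:
            return out
    raise EnumerationExhaustedError(
        f"only {len(out)} distinct non-canonical renderings of {smiles!r} "
        f"found in {budget} draws (requested {n})"
    )


@dataclass(frozen=True)
class PromptCompletionPair:
    """One fine-tuning unit: a SMILES prompt and its class-label completion."""

    prompt: str
    completion: str


def _pair_line(pair: PromptCompletionPair) -> str:
    return json.dumps(
        {"prompt": pair.prompt, "completion": pair.completion},
        separators=(",", ":"),
    )


def write_jsonl(pairs: Iterable[PromptCompletionPair], destination) -> None:
    """Write pairs as JSONL, one compact object per line.

    Key order is exactly ``prompt`` then ``completion`` with no whitespace
    beyond the newline, so output is byte-stable.
    """
    if hasattr(destination, "write"):
        for pair in pairs:
            destination.write(_pair_line(pair) + "\n")
        return
    with open(destination, "w", encoding="utf-8") as fh:
        for pair in pairs:
            fh.write(_pair_line(pair) + "\n")


def read_jsonl(source) -> list[PromptCompletionPair]:
    """Read prompt-completion pairs from JSONL, preserving order.

    The reader is liberal about whitespace but requires every non-blank line
    to be a JSON object with string values under both keys; otherwise a
    :class:`JsonlFormatError` reports the 1-based line number.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text(encoding="utf-8").splitlines()
    pairs: list[PromptCompletionPair] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise JsonlFormatError(lineno, f"not valid JSON: {exc}") from exc
        if not isinstance(obj, dict):
            raise JsonlFormatError(lineno, "line is not a JSON object")
        if "prompt" not in obj or "completion" not in obj:
            raise JsonlFormatError(
                lineno, "object must have 'prompt' and 'completion' keys"
            )
        pairs.append(
            PromptCompletionPair(str(obj["prompt"]), str(obj["completion"]))
        )
    return pairs
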
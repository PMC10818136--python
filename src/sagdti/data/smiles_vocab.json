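{
 "version": 1,
 "description": "Character-level SMILES vocabulary (organic subset); Cl/Br are single two-character atom tokens; id 0 is padding.",
 "tokens": [
  "<pad>",
  "C",
  "N",
  "O",
  "S",
  "P",
  "F",
  "Cl",
  "Br",
  "I",
  "H",
  "c",
  "n",
  "o",
  "s",
  "p",
  "0",
  "1",
  "2",
  "3",
  "4",
  "5",
  "6",
  "7",
  "8",
  "9",
  "(",
  ")",
  "[",
  "]",
  "=",
  "#",
  "@",
  "+",
  "-",
  "/",
  "\\",
  "."
 ],
 "atom_tokens": [
  "C",
  "N",
  "O",
  "S",
  "P",
  "F",
  "Cl",
  "Br",
  "I",
  "H",
  "c",
  "n",
  "o",
  "s",
  "p"
 ]
}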
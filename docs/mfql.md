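# The MFQL dialect implemented by lipidquery

This document is the normative grammar of the molecular fragmentation query
language (MFQL) as accepted by `lipidquery.mfql.parse_mfql`.

## Structure

A query consists of a `QUERYNAME` assignment followed by sections in any
order (each section keyword may appear more than once for `DEFINE`):

```
QUERYNAME = Phosphatidylcholine;

DEFINE headPC = 'C5 H15 O4 N1 P1' WITH CHG = +1;
DEFINE prPC   = 'C[30..48]H[30..200]N[1]O[8]P[1]' WITH CHG = +1, DBR = (1.5, 7.5);

IDENTIFY
    prPC IN MS1+ AND
    headPC IN MS2+

SUCHTHAT
    isEven(prPC.chemsc[C])

REPORT
    MASS   = prPC.mass;
    NAME   = "PC [%d:%d]" % "((prPC.chemsc - headPC.chemsc)[C] - 3, prPC.chemsc[db] - 1.5)";
    CHEMSC = prPC.chemsc;
    ERROR  = "%dppm" % "(prPC.errppm)";
    INTENS = prPC.intensity;
    FRAGINTENS = headPC.intensity;;
```

Statements end with `;`; stray extra semicolons are ignored.  `#` starts a
comment to end of line.

## Grammar (EBNF)

```
query        = "QUERYNAME" "=" NAME ";" { section } ;
section      = "DEFINE" { define }
             | "IDENTIFY" identify
             | "SUCHTHAT" expr ";"
             | "REPORT" { NAME "=" expr ";" } ;
define       = NAME "=" defbody [ "WITH" with { "," with } ] ";" ;
defbody      = SQSTRING            (* formula or bracket-range constraint *)
             | NUMBER              (* explicit m/z *)
             | "(" NUMBER { "," NUMBER } ")" ;   (* mass list *)
with         = "CHG" "=" [ "+" | "-" ] NUMBER
             | "DBR" "=" "(" number "," number ")" ;
identify     = clause { ("AND" | "OR") clause } ;
clause       = NAME "IN" ("MS1" | "MS2") ("+" | "-") ;

expr         = orexpr ;
orexpr       = andexpr { "OR" andexpr } ;
andexpr      = notexpr { "AND" notexpr } ;
notexpr      = [ "NOT" ] cmpexpr ;
cmpexpr      = addexpr [ ("<"|"<="|">"|">="|"=="|"!=") addexpr ] ;
addexpr      = mulexpr { ("+"|"-") mulexpr } ;
mulexpr      = unary { ("*"|"/") unary } ;
unary        = [ "+" | "-" ] postfix ;
postfix      = primary { "." NAME | "[" NAME "]" } ;
primary      = NUMBER | DQSTRING [ "%" DQSTRING ] | SQSTRING
             | NAME [ "(" [ expr { "," expr } ] ")" ]
             | "(" expr ")" ;
```

A formula string without brackets (`'C5 H15 O4 N1 P1'`) is an explicit sum
composition; with brackets (`'C[30..48]H[30..200]...'`) it is an
sc-constraint of per-element closed count ranges.  `C[8]` abbreviates
`C[8..8]`.

## Semantics

* `IDENTIFY v IN MS1±` binds `v` against every precursor entry of a
  MasterScan of that polarity: constraint-defined variables through
  exhaustive composition enumeration within the MS1 tolerance,
  explicit compositions / masses by direct m/z match.
* `IDENTIFY v IN MS2±` binds `v` inside the fragment block attached to the
  candidate precursor entry only, within the MS2 tolerance — a fragment is
  never searched outside the MS/MS spectra of its precursor.
* `AND` requires all clauses bound for an entry, `OR` any one; extra
  unrelated fragments in a block never prevent a match.
* `SUCHTHAT` filters candidate binding sets; unbound variables (possible
  under `OR`) make the containing filter fail for that set.
* Each surviving binding set yields one report row.  If several
  compositions match one peak within tolerance, each yields its own row
  (flagged ambiguous internally), never a silent merge.

### Peak attributes

| attribute       | value                                               |
|-----------------|-----------------------------------------------------|
| `v.mass`        | representative m/z of the matched peak              |
| `v.chemsc`      | bound sum composition                               |
| `v.chemsc[E]`   | count of element `E`                                |
| `v.chemsc[db]`  | double-bond equivalents of the bound composition    |
| `v.errppm`      | (observed − theoretical)/theoretical × 1e6          |
| `v.errda`       | observed − theoretical, Da                          |
| `v.intensity`   | per-acquisition intensity vector                    |
| `v.occupation`  | fraction of acquisitions containing the peak        |

Sum compositions support `+`, `-` (element-wise; negative counts are
errors) and element/`db` indexing.

### Functions

`isEven(x)`, `isOdd(x)`, `abs(x)`.

### Formatting

The two-string idiom `"fmt" % "(arg1, arg2, ...)"`: placeholders `%d`
(truncates toward zero), `%f` (default 1 decimal, `%.Nf` for N decimals),
`%s`.  Arity mismatches are evaluation errors.

### Neutral losses

A neutral loss is expressed arithmetically in `SUCHTHAT`, e.g.

```
SUCHTHAT abs(prec.mass - frag.mass - 74.0) < 0.3
```

rather than by a dedicated keyword: the filter language is ordinary
arithmetic over peak attributes.
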
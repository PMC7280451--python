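# Built-in derived-trait library.
# definition: ';'-separated condensed-notation motifs, or a classifier rule
#   'o_core:<classes>' / 'gsl_series:<classes>'.
# terminal: 'leaves' requires childless pattern residues to map onto leaves.
# forbidden: '<Residue>:<pos>[,<pos>...]' positions that must be unoccupied.
# allow_alditol: 'no' forbids pattern residues from matching the reducing-end
#   alditol.
name	scope	mode	definition	anchor	terminal	forbidden	allow_alditol	panel
Core 2/4	O	membership	o_core:core2,core4	anywhere	-	-	yes	4C
sTn antigen	O	membership	o_core:sTn	anywhere	-	-	yes	4D
T antigen	O	membership	Galβ1-3GalNAc-ol	at_root	leaves	GalNAc:6	yes	4E
Terminal GlcNAc	O	epitope_weighted	GlcNAc	anywhere	leaves	-	no	4F
Terminal GalNAc	O	epitope_weighted	GalNAc	anywhere	leaves	-	no	4G
Sia a2,3 -> Gal	O	epitope_weighted	Neu5Acα2-3Gal	anywhere	-	-	yes	4H
Sia a2,6 -> Gal	O	epitope_weighted	Neu5Acα2-6Gal	anywhere	-	-	yes	4I
Sia a2,6 -> GalNAc	O	epitope_weighted	Neu5Acα2-6GalNAc	anywhere	-	-	yes	4J
Fuc a1,2	O	epitope_weighted	Fucα1-2Gal	anywhere	-	-	yes	4K
Fuc a1,3/4	O	epitope_weighted	Fucα1-3GlcNAc;Fucα1-4GlcNAc	anywhere	-	-	yes	4L
sLeA	O	epitope_weighted	Neu5Acα2-3Galβ1-3(Fucα1-4)GlcNAc	anywhere	leaves	-	yes	4M
Lewis X	O	epitope_weighted	Galβ1-4(Fucα1-3)GlcNAc	anywhere	leaves	-	yes	-
Blood group H	O	epitope_weighted	Fucα1-2Gal	anywhere	leaves	Gal:3,4,6	yes	-
Blood group A	O	epitope_weighted	GalNAcα1-3(Fucα1-2)Gal	anywhere	leaves	-	yes	-
Globosides	GSL	class_partition	gsl_series:globo	anywhere	-	-	yes	5C
Gangliosides	GSL	class_partition	gsl_series:ganglio	anywhere	-	-	yes	5D
nsGSLs	GSL	class_partition	gsl_series:neolacto	anywhere	-	-	yes	5E
Lactose core only	GSL	class_partition	gsl_series:core_only	anywhere	-	-	yes	-
Other GSL	GSL	class_partition	gsl_series:other	anywhere	-	-	yes	-
Terminal GalNAc	GSL	epitope_weighted	GalNAc	anywhere	leaves	-	no	5F
Sia a2,3 -> Gal	GSL	epitope_weighted	Neu5Acα2-3Gal	anywhere	-	-	yes	5G
Sia a2,6 -> Gal	GSL	epitope_weighted	Neu5Acα2-6Gal	anywhere	-	-	yes	5H
Fuc a1,2	GSL	epitope_weighted	Fucα1-2Gal	anywhere	-	-	yes	5I
Fuc a1,3/4	GSL	epitope_weighted	Fucα1-3GlcNAc;Fucα1-4GlcNAc	anywhere	-	-	yes	5J
Lewis X	GSL	epitope_weighted	Galβ1-4(Fucα1-3)GlcNAc	anywhere	leaves	-	yes	5K
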
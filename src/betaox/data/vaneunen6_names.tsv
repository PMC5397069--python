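# sbml_id	canonical_name	class	chain_length
C16AcylCoACYT	C16AcylCoACYT	acyl-CoA	16
C16AcylCarCYT	C16AcylCarCYT	acyl-carnitine	16
C16AcylCarMAT	C16AcylCarMAT	acyl-carnitine	16
CarCYT	CarCYT	cofactor	NA
CoACYT	CoACYT	cofactor	NA
CarMAT	CarMAT	cofactor	NA
CoAMAT	CoAMAT	cofactor	NA
NADMAT	NADMAT	cofactor	NA
NADHMAT	NADHMAT	cofactor	NA
FADMAT	FADMAT	cofactor	NA
FADH2MAT	FADH2MAT	cofactor	NA
AcetylCoAMAT	AcetylCoAMAT	other	NA
C4AcylCoAMAT	C4AcylCoAMAT	acyl-CoA	4
C4EnoylCoAMAT	C4EnoylCoAMAT	enoyl-CoA	4
C4HydroxyacylCoAMAT	C4HydroxyacylCoAMAT	hydroxyacyl-CoA	4
C4KetoacylCoAMAT	C4KetoacylCoAMAT	ketoacyl-CoA	4
C6AcylCoAMAT	C6AcylCoAMAT	acyl-CoA	6
C6EnoylCoAMAT	C6EnoylCoAMAT	enoyl-CoA	6
C6HydroxyacylCoAMAT	C6HydroxyacylCoAMAT	hydroxyacyl-CoA	6
C6KetoacylCoAMAT	C6KetoacylCoAMAT	ketoacyl-CoA	6
C8AcylCoAMAT	C8AcylCoAMAT	acyl-CoA	8
C8EnoylCoAMAT	C8EnoylCoAMAT	enoyl-CoA	8
C8HydroxyacylCoAMAT	C8HydroxyacylCoAMAT	hydroxyacyl-CoA	8
C8KetoacylCoAMAT	C8KetoacylCoAMAT	ketoacyl-CoA	8
C10AcylCoAMAT	C10AcylCoAMAT	acyl-CoA	10
C10EnoylCoAMAT	C10EnoylCoAMAT	enoyl-CoA	10
C10HydroxyacylCoAMAT	C10HydroxyacylCoAMAT	hydroxyacyl-CoA	10
C10KetoacylCoAMAT	C10KetoacylCoAMAT	ketoacyl-CoA	10
C12AcylCoAMAT	C12AcylCoAMAT	acyl-CoA	12
C12EnoylCoAMAT	C12EnoylCoAMAT	enoyl-CoA	12
C12HydroxyacylCoAMAT	C12HydroxyacylCoAMAT	hydroxyacyl-CoA	12
C12KetoacylCoAMAT	C12KetoacylCoAMAT	ketoacyl-CoA	12
C14AcylCoAMAT	C14AcylCoAMAT	acyl-CoA	14
C14EnoylCoAMAT	C14EnoylCoAMAT	enoyl-CoA	14
C14HydroxyacylCoAMAT	C14HydroxyacylCoAMAT	hydroxyacyl-CoA	14
C14KetoacylCoAMAT	C14KetoacylCoAMAT	ketoacyl-CoA	14
C16AcylCoAMAT	C16AcylCoAMAT	acyl-CoA	16
C16EnoylCoAMAT	C16EnoylCoAMAT	enoyl-CoA	16
C16HydroxyacylCoAMAT	C16HydroxyacylCoAMAT	hydroxyacyl-CoA	16
C16KetoacylCoAMAT	C16KetoacylCoAMAT	ketoacyl-CoA	16
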
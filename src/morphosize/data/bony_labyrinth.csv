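abbreviation,name,kind,units,description
C0,Cochlea length,linear,mm,Cochlear apex to the base of the oval window
C1,Lateral semicircular canal length,linear,mm,Lateral-posterior canal junction to the base of the lateral ampulla
C2,Anterior semicircular canal length,linear,mm,Base of the anterior ampulla to the canal intersection point
C3,Posterior semicircular canal length,linear,mm,Canal intersection point to the base of the posterior ampulla
LABL,Bony labyrinth length,linear,mm,Cochlear apex to the top of the crus commune (overall inner-ear size proxy)
CRUL,Crus commune length,linear,mm,Canal intersection point to the base of the vestibular aqueduct
CRUC,Crus commune circumference,linear,mm,Circumference of the crus commune at the canal intersection point
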
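name	class_group	iri	definition	source
scidata	scientific data	sci:scientificData	Generic container for the data and metadata of one report	sdmo
discipline	scientific data	sci:discipline	Branch of science the report nominally belongs to	sdmo
subdiscipline	scientific data	sci:subdiscipline	Sub-branch of the discipline	sdmo
system	scientific data	sci:system	Section describing what the data is about	sdmo
facets	scientific data	sci:facets	Collection of system facets	sdmo
facet	scientific data	sci:facet	One component of the system description	sdmo
substance	scientific data	sci:substance	Facet describing a chemical substance	sdmo
condition	scientific data	sci:condition	Facet describing a condition under which data was recorded	sdmo
conditions	scientific data	sci:conditions	Collection of condition reports	sdmo
organism	scientific data	sci:organism	Facet describing a biological organism	sdmo
material	scientific data	sci:material	Facet describing a material	sdmo
name	scientific data	sci:name	Human-readable name of a facet subject	sdmo
formula	scientific data	sci:formula	Condensed chemical formula	sdmo
property	scientific data	sci:property	Name of the property a parameter reports	sdmo
quantity	scientific data	sci:quantity	Physical quantity associated with a property	sdmo
value	scientific data	sci:value	Numeric value report of a parameter	sdmo
number	scientific data	sci:number	The number carried by a numeric value	sdmo
numbertype	scientific data	sci:numbertype	Numeric type: decimal, integer, float or exponential	sdmo
sigfigs	scientific data	sci:sigfigs	Count of significant figures in a numeric value	sdmo
error	scientific data	sci:error	Reported uncertainty of a numeric value	sdmo
exact	scientific data	sci:exact	Whether a numeric value is an exact number	sdmo
textstring	scientific data	sci:textstring	Textual value report of a parameter	sdmo
text	scientific data	sci:text	The text carried by a textual value	sdmo
texttype	scientific data	sci:texttype	Text encoding type: plain, JSON, XML or HTML	sdmo
language	scientific data	sci:language	BCP-47 language tag of a textual value	sdmo
methodology	methodology	sci:methodology	Section describing how the data was obtained	sdmo
evaluation	methodology	sci:evaluation	Approach used: experimental, computational or theoretical	sdmo
aspects	methodology	sci:aspects	Collection of methodology aspects	sdmo
aspect	methodology	sci:aspect	One component of the methodology description	sdmo
measurement	methodology	sci:measurement	Aspect describing a measurement	sdmo
procedure	methodology	sci:procedure	Aspect describing a procedure	sdmo
resource	methodology	sci:resource	Aspect describing a resource used	sdmo
calculation	methodology	sci:calculation	Aspect describing a computational calculation	sdmo
basisset	methodology	sci:basisset	Aspect describing a quantum-chemical basis set	sdmo
software	methodology	sci:software	Aspect describing software used	sdmo
settings	methodology	sci:settings	Collection of instrument or software settings	sdmo
setting	methodology	sci:setting	One instrument or software setting	sdmo
technique	methodology	sci:technique	Named experimental technique	sdmo
instrument	methodology	sci:instrument	Instrument used for a measurement	sdmo
method	methodology	sci:method	Named computational or analytical method	sdmo
dataset	dataset	sci:dataset	Generic container for data reported as a set	sdmo
datagroup	dataset	sci:datagroup	Nestable aggregate of dataset elements	sdmo
dataseries	dataset	sci:dataseries	Ordered correlated array of data	sdmo
datapoint	dataset	sci:datapoint	Individual piece of data with no implied relation to others	sdmo
parameter	dataset	sci:parameter	Generic property report used for data and metadata	sdmo
attributes	dataset	sci:attributes	Parameters attached to a datagroup	sdmo
attribute	dataset	sci:attribute	One parameter attached to a datagroup	sdmo
source	dataset	sci:source	Link from data to the methodology aspect it came from	sdmo
scope	dataset	sci:scope	Link from data to the system facet it is about	sdmo
values	dataset	sci:values	Inline array of data carried by a dataseries	sdmo
valuerefs	dataset	sci:valuerefs	Array of internal links to datapoint data	sdmo
members	dataset	sci:members	Elements aggregated by a datagroup	sdmo
label	dataset	sci:label	Human-readable label of a dataset element	sdmo
kind	dataset	sci:kind	Kind descriptor of a datagroup	sdmo
properties	dataset	sci:properties	List of the properties reported in the data	sdmo
datum	dataset	sci:datum	One entry of a dataseries value array	sdmo
unit	unit of measure	sci:unit	In-place unit definition	sdmo
units	unit of measure	sci:units	Unit associated with the axis of a dataseries	sdmo
unitstr	unit of measure	sci:unitstr	Opaque, undefined unit string	sdmo
unitref	unit of measure	sci:unitref	Reference to a unit defined elsewhere	sdmo
symbol	unit of measure	sci:symbol	Printable symbol of a unit	sdmo
quantitykind	unit of measure	sci:quantitykind	Kind of physical quantity a unit measures	sdmo
dimensions	unit of measure	sci:dimensions	SI base-dimension exponents of a unit	sdmo
multiplier	unit of measure	sci:multiplier	Multiplicative factor converting a unit to coherent SI	sdmo
offset	unit of measure	sci:offset	Additive offset converting a unit to coherent SI	sdmo
prefix	unit of measure	sci:prefix	SI prefix applied to a unit	sdmo
uid	metadata	sci:uid	Unique identifier of the data packet	sdmo
version	metadata	sci:version	Version of the data packet	sdmo
generatedat	metadata	sci:generatedat	Timestamp at which the packet was generated	sdmo
permalink	metadata	sci:permalink	Permanent link to the packet	sdmo
startdate	metadata	sci:startdate	Date the reported work started	sdmo
toc	context	sci:toc	Table of contents: kinds of aspects, facets and dataset elements present	sdmo
title	metadata	http://purl.org/dc/terms/title	Title of the data packet	dcterms
authors	metadata	http://purl.org/dc/terms/creator	Authors of the data packet	dcterms
publisher	metadata	http://purl.org/dc/terms/publisher	Publisher of the data packet	dcterms
rights	metadata	http://purl.org/dc/terms/rights	Rights statement	dcterms
license	metadata	http://purl.org/dc/terms/license	License of the data	dcterms
description	metadata	http://purl.org/dc/terms/description	Free-text description	dcterms
date	metadata	http://purl.org/dc/terms/date	Date associated with the packet	dcterms
sources	metadata	http://purl.org/dc/terms/source	Works the packet data was derived from	dcterms
citation	metadata	http://purl.org/dc/terms/bibliographicCitation	Bibliographic citation of an original source	dcterms
url	metadata	http://purl.org/dc/terms/identifier	Resolvable identifier of an original source	dcterms
inchikey	scientific data	http://semanticscience.org/resource/CHEMINF_000059	Hashed InChI identifier of a substance	cheminf
inchi	scientific data	http://semanticscience.org/resource/CHEMINF_000113	InChI identifier of a substance	cheminf
casrn	scientific data	http://semanticscience.org/resource/CHEMINF_000446	CAS registry number of a substance	cheminf
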
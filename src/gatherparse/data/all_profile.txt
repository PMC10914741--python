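gbifID
datasetKey
occurrenceID
kingdom
phylum
class
order
family
genus
species
infraspecificEpithet
taxonRank
scientificName
scientificNameAuthorship
verbatimScientificName
taxonKey
speciesKey
countryCode
locality
municipality
county
stateProvince
occurrenceStatus
individualCount
decimalLatitude
decimalLongitude
coordinateUncertaintyInMeters
coordinatePrecision
elevation
elevationAccuracy
habitat
fieldNotes
eventDate
day
month
year
verbatimEventDate
basisOfRecord
institutionCode
collectionCode
catalogNumber
recordNumber
recordedBy
identifiedBy
dateIdentified
typeStatus
establishmentMeans
license
rightsHolder
datasetName
publishingOrgKey
lastInterpreted
mediaType
type
modified
language
rights
accessRights
bibliographicCitation
references
institutionID
collectionID
datasetID
ownerInstitutionCode
informationWithheld
dataGeneralizations
dynamicProperties
occurrenceRemarks
organismQuantity
organismQuantityType
sex
lifeStage
reproductiveCondition
behavior
caste
vitality
degreeOfEstablishment
pathway
georeferenceVerificationStatus
preparations
disposition
associatedMedia
associatedOccurrences
associatedReferences
associatedSequences
associatedTaxa
otherCatalogNumbers
recordedByID
identifiedByID
organismID
organismName
organismScope
associatedOrganisms
previousIdentifications
organismRemarks
materialSampleID
eventID
parentEventID
eventTime
startDayOfYear
endDayOfYear
samplingProtocol
sampleSizeValue
sampleSizeUnit
samplingEffort
eventRemarks
fieldNumber
locationID
higherGeographyID
higherGeography
continent
waterBody
islandGroup
island
country
verbatimLocality
minimumElevationInMeters
maximumElevationInMeters
verbatimElevation
minimumDepthInMeters
maximumDepthInMeters
verbatimDepth
depth
depthAccuracy
minimumDistanceAboveSurfaceInMeters
maximumDistanceAboveSurfaceInMeters
locationAccordingTo
locationRemarks
verbatimCoordinates
verbatimLatitude
verbatimLongitude
verbatimCoordinateSystem
verbatimSRS
geodeticDatum
footprintWKT
footprintSRS
footprintSpatialFit
georeferencedBy
georeferencedDate
georeferenceProtocol
georeferenceSources
georeferenceRemarks
pointRadiusSpatialFit
geologicalContextID
earliestEonOrLowestEonothem
latestEonOrHighestEonothem
earliestEraOrLowestErathem
latestEraOrHighestErathem
earliestPeriodOrLowestSystem
latestPeriodOrHighestSystem
earliestEpochOrLowestSeries
latestEpochOrHighestSeries
earliestAgeOrLowestStage
latestAgeOrHighestStage
lowestBiostratigraphicZone
highestBiostratigraphicZone
lithostratigraphicTerms
group
formation
member
bed
identificationID
verbatimIdentification
identificationQualifier
identificationReferences
identificationVerificationStatus
identificationRemarks
taxonID
scientificNameID
acceptedNameUsageID
parentNameUsageID
originalNameUsageID
nameAccordingToID
namePublishedInID
taxonConceptID
acceptedNameUsage
parentNameUsage
originalNameUsage
nameAccordingTo
namePublishedIn
namePublishedInYear
higherClassification
subgenus
specificEpithet
genericName
infragenericEpithet
cultivarEpithet
vernacularName
nomenclaturalCode
taxonomicStatus
nomenclaturalStatus
taxonRemarks
verbatimTaxonRank
acceptedTaxonKey
kingdomKey
phylumKey
classKey
orderKey
familyKey
genusKey
subgenusKey
acceptedScientificName
typifiedName
protocol
lastParsed
lastCrawled
repatriated
relativeOrganismQuantity
projectId
programmeAcronym
publishingCountry
installationKey
hostingOrganizationKey
networkKeys
isInCluster
isSequenced
hasCoordinate
hasGeospatialIssues
level0Gid
level0Name
level1Gid
level1Name
level2Gid
level2Name
level3Gid
level3Name
iucnRedListCategory
distanceFromCentroidInMeters
gbifRegion
publishedByGbifRegion
crawlId
verbatimLabel
superfamily
subfamily
tribe
subtribe
measurementID
measurementType
measurementValue
measurementAccuracy
measurementUnit
measurementDeterminedBy
measurementDeterminedDate
measurementMethod
measurementRemarks
parentMeasurementID
resourceRelationshipID
resourceID
relatedResourceID
relationshipOfResource
relationshipAccordingTo
relationshipEstablishedDate
relationshipRemarks
relationshipOfResourceID
identifier
coordinateAccuracy
issue
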